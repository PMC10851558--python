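"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment scores
come from exhaustive path enumeration, clustering heights from a naive
O(n^3) agglomeration, rank correlations from direct rank arithmetic.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=None)
def _paths(n: int, m: int) -> tuple[str, ...]:
    """All monotone alignment move strings from (0,0) to (n,m).

    Moves: D = aligned pair, X = residue of a against a gap,
    Y = residue of b against a gap.
    """
    if n == 0 and m == 0:
        return ("",)
    out = []
    if n > 0 and m > 0:
        out += [p + "D" for p in _paths(n - 1, m - 1)]
    if n > 0:
        out += [p + "X" for p in _paths(n - 1, m)]
    if m > 0:
        out += [p + "Y" for p in _paths(n, m - 1)]
    return tuple(out)


def brute_force_align_score(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Optimal global affine-gap score by scoring every alignment path.

    A gap of length L costs gap_open + gap_extend * L.  Exponential in
    the input lengths; intended for sequences of <= 6 residues.
    """
    best = -np.inf
    for path in _paths(len(a), len(b)):
        i = j = 0
        score = 0.0
        prev = ""
        for move in path:
            if move == "D":
                score += _BLOSUM62[a[i], b[j]]
                i += 1
                j += 1
            else:
                if move != prev:
                    score -= gap_open + gap_extend
                else:
                    score -= gap_extend
                if move == "X":
                    i += 1
                else:
                    j += 1
            prev = move
        best = max(best, score)
    return float(best)


def spearman_rho_oracle(x: list[float], y: list[float]) -> float:
    """Spearman correlation from first principles: Pearson on mid-ranks."""

    def ranks(v: list[float]) -> list[float]:
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mid = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = mid
            i = j + 1
        return r

    rx, ry = np.array(ranks(x)), np.array(ranks(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def upgma_oracle(dist: np.ndarray, labels: list[str]):
    """Naive average-linkage agglomeration.

    Returns the merge history as (frozenset_a, frozenset_b, height)
    tuples; cluster distance is the unweighted mean of member pair
    distances (UPGMA).
    """
    clusters: list[frozenset] = [frozenset([l]) for l in labels]
    index = {l: i for i, l in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = float(
                    np.mean(
                        [
                            dist[index[a], index[b]]
                            for a in clusters[i]
                            for b in clusters[j]
                        ]
                    )
                )
                key = (d, tuple(sorted(clusters[i]))[0], tuple(sorted(clusters[j]))[0])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def ex90_oracle(values, quantile: float = 0.9) -> int:
    """Smallest k such that the k largest values reach 90% of the total."""
    v = sorted(values, reverse=True)
    total = sum(v)
    acc = 0.0
    for k, x in enumerate(v, start=1):
        acc += x
        if acc >= quantile * total:
            return k
    return len(v)
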