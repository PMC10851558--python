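"""Genome clustering from shared gene content.

The binary presence/absence matrix of the gene array is reduced to a
genome-by-genome distance (1 - Spearman rank correlation of presence
columns) and clustered hierarchically, yielding a gene-content
dendrogram comparable to whole-genome phylogenies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history over genome leaves plus its newick form."""

    merges: tuple[tuple[int, int, float], ...]
    labels: tuple[str, ...]
    newick: str
    linkage_matrix: np.ndarray


def spearman_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise distance d = 1 - Spearman rho between genome columns.

    Identical presence profiles give d = 0, perfectly complementary ones
    d = 2.  A zero-variance column (all-present or all-absent genome)
    has no rank correlation and raises an error naming the genome.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two genomes")
    for gid in matrix.columns:
        col = matrix[gid].to_numpy()
        if col.max() == col.min():
            raise ValueError(f"zero-variance presence column for genome {gid!r}")
        if col.sum() == 0:
            raise ValueError(f"genome {gid!r} has no genes present")
    rho = stats.spearmanr(matrix.to_numpy()).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def hierarchical_cluster(
    distance: pd.DataFrame, linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix.

    ``linkage`` is one of ``average`` (UPGMA-style, the default),
    ``complete`` or ``single``.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    d = distance.to_numpy(float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    labels = tuple(str(c) for c in distance.columns)
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    merges = tuple((int(a), int(b), float(h)) for a, b, h, _ in Z)
    return Dendrogram(
        merges=merges,
        labels=labels,
        newick=_to_newick(Z, labels),
        linkage_matrix=Z,
    )


def _to_newick(Z: np.ndarray, labels: tuple[str, ...]) -> str:
    n = len(labels)

    def node(i: int, parent_height: float) -> str:
        if i < n:
            return f"{labels[i]}:{parent_height:.6g}"
        a, b, h, _ = Z[i - n]
        branch = parent_height - h
        return f"({node(int(a), h)},{node(int(b), h)}):{branch:.6g}"

    root_height = float(Z[-1, 2])
    a, b = int(Z[-1, 0]), int(Z[-1, 1])
    return f"({node(a, root_height)},{node(b, root_height)});"


def leaves_under(dendrogram: Dendrogram, merge_index: int) -> set[str]:
    """Leaf labels below a given merge (cluster) of the dendrogram."""
    n = len(dendrogram.labels)

    def collect(i: int) -> set[str]:
        if i < n:
            return {dendrogram.labels[i]}
        a, b, _ = dendrogram.merges[i - n]
        return collect(a) | collect(b)

    return collect(n + merge_index)


def clades(dendrogram: Dendrogram) -> list[set[str]]:
    """All non-trivial clades (leaf sets of internal nodes)."""
    return [leaves_under(dendrogram, i) for i in range(len(dendrogram.merges))]
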