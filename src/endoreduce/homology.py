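"""Protein-level homology of endosymbiont genes to a free-living reference.

Each query protein is aligned globally (Needleman-Wunsch with affine
gaps, BLOSUM62 by default) against a reference proteome; the best hit by
score, percent identity over the trimmed alignment, relative length and
a reciprocal-best-hit (RBH) flag make up a :class:`HomologAssignment`.
Gap costs follow the BLAST convention: a gap of length L costs
``gap_open + gap_extend * L``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class HomologAssignment:
    """One query gene's link to its reference-proteome homolog."""

    query_gene: str
    ref_gene: str | None
    score: float
    identity: float
    relative_length: float
    reciprocal: bool

    def __post_init__(self) -> None:
        if self.ref_gene is not None and not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.reciprocal and self.ref_gene is None:
            raise ValueError("reciprocal assignment requires a ref gene")


@dataclass(frozen=True)
class AlignmentResult:
    aligned_query: str
    aligned_ref: str
    score: float

    @property
    def columns(self) -> int:
        return len(self.aligned_query)


def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # PairwiseAligner charges open_gap_score for the first gap residue and
    # extend_gap_score for each further one; shift so a length-L gap costs
    # gap_open + gap_extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    return "".join(c if c in alphabet else "X" for c in seq)


def global_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    aligner: Align.PairwiseAligner | None = None,
) -> AlignmentResult:
    """Optimal global alignment of two protein sequences.

    Returns the two gapped rows and the optimal affine-gap score.
    Non-standard residues are mapped to X.  Raises on empty input.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if aligner is None:
        aligner = make_aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    a, b = _sanitize(a, alphabet), _sanitize(b, alphabet)
    aln = aligner.align(a, b)
    best = aln[0]  # deterministic first traceback
    ta, tb = best[0], best[1]
    return AlignmentResult(aligned_query=str(ta), aligned_ref=str(tb), score=float(best.score))


def percent_identity(
    alignment: AlignmentResult, denominator: str = "alignment"
) -> float:
    """Percent identical columns of a pairwise alignment.

    ``denominator`` selects the column count: ``alignment`` (terminal-gap
    columns trimmed, internal gaps kept — the default), ``shorter`` or
    ``longer`` (ungapped sequence lengths).
    """
    qa, ra = alignment.aligned_query, alignment.aligned_ref
    if len(qa) != len(ra) or not qa:
        raise ValueError("malformed alignment")
    # trim columns that are terminal gaps in either row
    start, end = 0, len(qa)
    while start < end and (qa[start] == "-" or ra[start] == "-"):
        if _is_terminal_gap(qa, ra, start, leading=True):
            start += 1
        else:
            break
    while end > start and (qa[end - 1] == "-" or ra[end - 1] == "-"):
        if _is_terminal_gap(qa, ra, end - 1, leading=False):
            end -= 1
        else:
            break
    ident = sum(
        1 for i in range(start, end) if qa[i] == ra[i] and qa[i] != "-"
    )
    if denominator == "alignment":
        denom = end - start
    elif denominator == "shorter":
        denom = min(len(qa.replace("-", "")), len(ra.replace("-", "")))
    elif denominator == "longer":
        denom = max(len(qa.replace("-", "")), len(ra.replace("-", "")))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero-length trimmed alignment")
    return 100.0 * ident / denom


def _is_terminal_gap(qa: str, ra: str, i: int, leading: bool) -> bool:
    row = qa if qa[i] == "-" else ra
    return set(row[: i + 1] if leading else row[i:]) == {"-"}


def _best_hit(
    scores: dict[str, float], order: list[str]
) -> tuple[str, float]:
    best = max(scores.values())
    candidates = sorted(g for g in order if scores[g] == best)
    return candidates[0], best


def reciprocal_best_hits(
    query_proteome: dict[str, str],
    ref_proteome: dict[str, str],
    min_score: float = 40.0,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[HomologAssignment]:
    """All-vs-all global alignment and reciprocal-best-hit assignment.

    The best reference hit per query is chosen by score (ties broken by
    identity, then lexicographic gene id).  ``reciprocal`` is true iff
    the pair are each other's best hit.  Queries whose best score falls
    below ``min_score`` are left unassigned (``ref_gene=None``) — these
    are the severely deteriorated genes.
    """
    if not query_proteome or not ref_proteome:
        raise ValueError("both proteomes must be non-empty")
    aligner = make_aligner(matrix, gap_open, gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet)
    q_clean = {k: _sanitize(v, alphabet) for k, v in query_proteome.items()}
    r_clean = {k: _sanitize(v, alphabet) for k, v in ref_proteome.items()}
    ref_ids = sorted(r_clean)
    query_ids = sorted(q_clean)

    # score-only pass (no traceback) for the full cross product
    score_q: dict[str, dict[str, float]] = {}
    for q in query_ids:
        score_q[q] = {r: float(aligner.score(q_clean[q], r_clean[r])) for r in ref_ids}
    best_of_ref: dict[str, str] = {}
    for r in ref_ids:
        col = {q: score_q[q][r] for q in query_ids}
        best_of_ref[r], _ = _best_hit(col, query_ids)

    assignments: list[HomologAssignment] = []
    for q in query_ids:
        row = score_q[q]
        best_score = max(row.values())
        tied = sorted(r for r in ref_ids if row[r] == best_score)
        if len(tied) > 1:
            # break ties by identity, then id
            scored = []
            for r in tied:
                aln = global_align(q_clean[q], r_clean[r], aligner=aligner)
                scored.append((-percent_identity(aln), r))
            tied = [r for _, r in sorted(scored)]
        best_ref = tied[0]
        if best_score < min_score:
            assignments.append(
                HomologAssignment(q, None, best_score, 0.0, 0.0, False)
            )
            continue
        aln = global_align(q_clean[q], r_clean[best_ref], aligner=aligner)
        identity = percent_identity(aln)
        rel_len = 100.0 * len(q_clean[q]) / len(r_clean[best_ref])
        reciprocal = best_of_ref[best_ref] == q
        assignments.append(
            HomologAssignment(q, best_ref, best_score, identity, rel_len, reciprocal)
        )
    return assignments


def assignments_frame(
    assignments: list[HomologAssignment], genome_id: str = ""
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query_genome": genome_id,
                "query_gene": a.query_gene,
                "ref_gene": a.ref_gene if a.ref_gene is not None else "",
                "score": a.score,
                "identity": a.identity,
                "relative_length": a.relative_length,
                "reciprocal": a.reciprocal,
            }
            for a in assignments
        ]
    )
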