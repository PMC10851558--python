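"""Genome- and gene-level base-composition statistics.

Reduced endosymbiont genomes drift toward A/T under relaxed selection, so
%GC is the central erosion readout here: whole-genome sliding-window
profiles, per-gene %GC distributions for protein-coding genes (PCGs),
intergenic-distance summaries, and a census of genes carrying long A/T
homopolymer runs (candidate internal priming sites in poly-dT selected
RNA libraries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeRecord


def gc_percent(seq: str) -> float:
    """G+C percentage of a nucleotide sequence; N bases are ignored.

    Raises ``ValueError`` on an empty or all-N sequence.
    """
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence empty (or all N); %GC undefined")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def at_percent(seq: str) -> float:
    return 100.0 - gc_percent(seq)


@dataclass(frozen=True)
class GcProfile:
    """Sliding-window %GC track along one genome."""

    window: int
    step: int
    positions: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"start": self.positions, "value": self.values})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def sliding_window_gc(
    genome: GenomeRecord | str,
    window: int,
    step: int,
    wrap_final: bool = False,
) -> GcProfile:
    """%GC in sliding windows; only full windows are emitted.

    With ``wrap_final`` on a circular genome, trailing windows wrap
    through the origin so the whole replicon is covered.
    """
    seq = genome if isinstance(genome, str) else genome.sequence
    circular = False if isinstance(genome, str) else genome.circular
    n = len(seq)
    if not (0 < step <= window):
        raise ValueError(f"need 0 < step <= window, got step={step} window={window}")
    if window > n:
        raise ValueError(f"window {window} exceeds genome length {n}")
    limit = n if (wrap_final and circular) else n - window + 1
    positions = np.arange(0, limit, step, dtype=int)
    values = np.empty(len(positions))
    padded = seq + seq[:window] if (wrap_final and circular) else seq
    for i, p in enumerate(positions):
        values[i] = gc_percent(padded[p : p + window])
    return GcProfile(window=window, step=step, positions=positions, values=values)


def pcg_gc_table(genomes: list[GenomeRecord], include_pseudo: bool = False) -> pd.DataFrame:
    """One row per protein-coding gene: genome, gene, length, %GC."""
    rows = []
    for g in genomes:
        for gene in g.coding_genes(include_pseudo=include_pseudo):
            rows.append(
                {
                    "genome_id": g.genome_id,
                    "gene_id": gene.gene_id,
                    "length": gene.length,
                    "gc_percent": gc_percent(gene.extract(g.sequence)),
                }
            )
    return pd.DataFrame(rows)


def pcg_gc_stats(
    genomes: list[GenomeRecord],
    bin_width: float = 1.0,
    include_pseudo: bool = False,
) -> dict:
    """Pooled and per-genome PCG %GC summaries plus a binned histogram.

    The pooled mean is unweighted over every gene of every genome (each
    gene counts once regardless of its genome of origin); SD is the
    sample SD (n-1).
    """
    table = pcg_gc_table(genomes, include_pseudo=include_pseudo)
    if table.empty:
        raise ValueError("no protein-coding genes in input")
    per_genome = (
        table.groupby("genome_id")["gc_percent"]
        .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size")
        .reset_index()
    )
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    hist, _ = np.histogram(table["gc_percent"], bins=edges)
    return {
        "table": table,
        "pooled_mean": float(table["gc_percent"].mean()),
        "pooled_sd": float(table["gc_percent"].std(ddof=1)),
        "n_genes": int(len(table)),
        "per_genome": per_genome,
        "hist_edges": edges,
        "hist_counts": hist,
    }


def mean_pcg_length(genome: GenomeRecord, include_pseudo: bool = False) -> float:
    cds = genome.coding_genes(include_pseudo=include_pseudo)
    if not cds:
        raise ValueError(f"{genome.genome_id}: no protein-coding genes")
    return float(np.mean([g.length for g in cds]))


def intergenic_stats(
    genome: GenomeRecord,
    include_rnas: bool = True,
    include_pseudo: bool = False,
    wrap: bool | None = None,
) -> dict:
    """Signed gaps between consecutive genes and their mean.

    Overlapping genes yield negative gaps that are retained in the mean
    (clipping would bias it upward).  On circular genomes the wrap gap
    from the last gene back to the first is included by default.
    """
    genes = [
        g
        for g in genome.genes
        if (include_rnas or g.kind == "CDS") and (include_pseudo or not g.pseudo)
    ]
    if len(genes) < 2:
        raise ValueError(f"{genome.genome_id}: need >=2 genes for intergenic stats")
    genes = sorted(genes, key=lambda g: g.start)
    gaps = [genes[i + 1].start - genes[i].spans[-1][1] for i in range(len(genes) - 1)]
    if wrap is None:
        wrap = genome.circular
    if wrap:
        gaps.append(len(genome) - genes[-1].spans[-1][1] + genes[0].start)
    return {"gaps": gaps, "mean": float(np.mean(gaps)), "n": len(gaps)}


def _has_run(seq: str, bases: set[str], min_run: int) -> bool:
    run_base, run_len = "", 0
    for b in seq:
        if b == run_base:
            run_len += 1
        else:
            run_base, run_len = b, 1
        if run_base in bases and run_len >= min_run:
            return True
    return False


def homopolymer_gene_census(
    genome: GenomeRecord,
    bases: set[str] = frozenset({"A", "T"}),
    min_run: int = 10,
    kinds: tuple[str, ...] | None = None,
    include_pseudo: bool = False,
) -> tuple[int, list[str]]:
    """Genes whose span contains a single-base run of length >= ``min_run``.

    A gene counts once if any base in ``bases`` forms such a run within
    its annotated span (scanned on the forward strand of the record —
    for the {A, T} set runs are strand-symmetric).  ``kinds`` restricts
    the census, e.g. ``("CDS",)`` for protein-coding genes only.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    bases = {b.upper() for b in bases}
    hits = []
    for g in genome.genes:
        if kinds is not None and g.kind not in kinds:
            continue
        if g.pseudo and not include_pseudo:
            continue
        span_seq = "".join(genome.sequence[s:e] for s, e in g.spans)
        if _has_run(span_seq, bases, min_run):
            hits.append(g.gene_id)
    return len(hits), hits
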