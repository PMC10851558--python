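"""Expression summaries for endosymbiont transcripts.

Counts-per-million on a log2 scale (logCPM) with an edgeR-style prior,
low/medium/high expression tiers, the Ex90 statistic (number of
transcripts accounting for 90% of total expression), mapping-fraction
bookkeeping, and a contingency test of expression tier against
conservation quadrant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TIERS = ("low", "mid", "high")


@dataclass
class ExpressionTable:
    """Gene-by-sample read counts with per-sample library sizes."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0)
        self.lib_sizes = self.lib_sizes.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def read_tsv(cls, path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def log_cpm(table: ExpressionTable, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudo-count.

    logCPM = log2( (count + prior) / (lib_size + 2*prior) * 1e6 ), the
    edgeR convention; ``prior=0`` gives plain log2 CPM (and -inf for
    zero counts).
    """
    if (table.lib_sizes <= 0).any():
        bad = list(table.lib_sizes.index[table.lib_sizes <= 0])
        raise ValueError(f"zero/negative library sizes for samples {bad}")
    counts = table.counts.to_numpy(float)
    libs = table.lib_sizes.to_numpy(float)
    with np.errstate(divide="ignore"):
        vals = np.log2((counts + prior) / (libs + 2.0 * prior) * 1e6)
    return pd.DataFrame(vals, index=table.counts.index, columns=table.counts.columns)


def tier_classify(logcpm: float, lo: float = 9.0, hi: float = 11.0) -> str:
    """low (< lo), mid (lo..hi inclusive) or high (> hi) expression."""
    if logcpm < lo:
        return "low"
    if logcpm > hi:
        return "high"
    return "mid"


def tier_table(
    logcpm: pd.DataFrame, lo: float = 9.0, hi: float = 11.0
) -> pd.Series:
    """Per-gene tier from the mean logCPM across samples."""
    means = logcpm.mean(axis=1)
    return means.map(lambda v: tier_classify(v, lo, hi))


def ex90(expression: np.ndarray | pd.Series | list, quantile: float = 0.9) -> int:
    """Smallest number of genes whose summed expression reaches 90% of
    the total.  Scale- and order-invariant."""
    v = np.asarray(expression, dtype=float)
    if v.size == 0:
        raise ValueError("empty expression vector")
    if (v < 0).any():
        raise ValueError("negative expression values")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero expression vector")
    ordered = np.sort(v)[::-1]
    cum = np.cumsum(ordered)
    return int(np.searchsorted(cum, quantile * total) + 1)


def mapping_fraction(mapped: int, total: int) -> float:
    """Percentage of sequencing reads that mapped to the genome."""
    if total <= 0:
        raise ValueError("total reads must be positive")
    if not (0 <= mapped <= total):
        raise ValueError("need 0 <= mapped <= total")
    return 100.0 * mapped / total


def tier_quadrant_overlay(
    tiers: dict[str, str], quadrants: dict[str, str]
) -> dict:
    """Contingency table of expression tier vs conservation quadrant,
    with a chi-squared independence test.

    If %GC erosion drove expression, tiers would be associated with the
    quadrants; independence (large p) argues against that.
    """
    common = sorted(set(tiers) & set(quadrants))
    if not common:
        raise ValueError("no genes shared between tier and quadrant maps")
    quadrant_levels = ("Q1", "Q2", "Q3", "Q4")
    table = pd.DataFrame(0, index=list(TIERS), columns=list(quadrant_levels))
    for g in common:
        table.loc[tiers[g], quadrants[g]] += 1
    # drop empty rows/cols for the test; chi2 needs positive marginals
    trimmed = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if trimmed.shape[0] < 2 or trimmed.shape[1] < 2:
        chi2, p, dof = float("nan"), float("nan"), 0
    else:
        chi2, p, dof, expected = stats.chi2_contingency(trimmed.to_numpy())
        if (expected < 5).any():
            warnings.warn("chi-squared expected counts below 5; test is approximate")
    return {"table": table, "chi2": float(chi2), "p_value": float(p), "dof": int(dof), "n": len(common)}
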