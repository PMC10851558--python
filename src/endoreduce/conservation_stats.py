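"""Gene %GC versus homolog-identity framework.

Protein-coding genes of a reduced genome are characterized by two
coupled erosion readouts: their %GC content and their percent protein
identity to the homolog in a free-living reference.  Genes are placed in
four quadrants around the pooled means of the two axes, gene categories
are overlaid as quadrant count summaries, and an ordinary least squares
model quantifies how identity responds to %GC and to gene length
conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class QuadrantThresholds:
    """The %GC and identity means that split the plane into quadrants."""

    gc_mean: float
    identity_mean: float

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "QuadrantThresholds":
        return cls(
            gc_mean=float(table["gc_percent"].mean()),
            identity_mean=float(table["identity"].mean()),
        )


@dataclass(frozen=True)
class RegressionFit:
    intercept: float
    coef_gc: float
    coef_len: float
    standardized_coef_gc: float
    standardized_coef_len: float
    se_gc: float
    se_len: float
    p_gc: float
    p_len: float
    r_squared: float
    n: int

    def ci95_gc(self) -> tuple[float, float]:
        """95% confidence interval for the %GC coefficient (t-based)."""
        tcrit = stats.t.ppf(0.975, df=self.n - 3)
        return (self.coef_gc - tcrit * self.se_gc, self.coef_gc + tcrit * self.se_gc)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def quadrant_classify(gc: float, identity: float, t: QuadrantThresholds) -> str:
    """Quadrant of one gene; exact ties go to the 'above' side.

    Q1: high GC / low identity; Q2: low on both; Q3: high on both;
    Q4: low GC / high identity.
    """
    high_gc = gc >= t.gc_mean
    high_id = identity >= t.identity_mean
    if high_gc and high_id:
        return "Q3"
    if high_gc:
        return "Q1"
    if high_id:
        return "Q4"
    return "Q2"


def classify_table(
    table: pd.DataFrame, thresholds: QuadrantThresholds | None = None
) -> pd.DataFrame:
    """Add a ``quadrant`` column; thresholds default to the pooled means
    of the supplied table (they are dataset-specific, not universal)."""
    if thresholds is None:
        thresholds = QuadrantThresholds.from_table(table)
    out = table.copy()
    out["quadrant"] = [
        quadrant_classify(gc, ident, thresholds)
        for gc, ident in zip(out["gc_percent"], out["identity"])
    ]
    return out


def quadrant_summary(
    classified: pd.DataFrame, category: set[str] | None = None
) -> dict[str, int]:
    """Quadrant counts, optionally restricted to a gene-id category
    (e.g. amino-acid-biosynthesis genes, ribosomal genes, hypotheticals)."""
    sub = classified
    if category is not None:
        present = classified["gene_id"].isin(category)
        missing = len(category) - classified.loc[present, "gene_id"].nunique()
        if missing > 0:
            import warnings

            warnings.warn(f"{missing} category gene ids absent from classified set")
        sub = classified[present]
    counts = sub["quadrant"].value_counts()
    return {q: int(counts.get(q, 0)) for q in QUADRANTS}


def fit_identity_model(table: pd.DataFrame) -> RegressionFit:
    """OLS of homolog identity on gene %GC and relative length.

    Standardized coefficients come from refitting on z-scored predictors
    and response.  Raises on rank-deficient (collinear) designs.
    """
    needed = {"identity", "gc_percent", "relative_length"}
    if not needed.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(needed)}")
    d = table.dropna(subset=sorted(needed))
    n = len(d)
    if n < 3:
        raise ValueError(f"need at least 3 rows, got {n}")
    X = d[["gc_percent", "relative_length"]].to_numpy(float)
    y = d["identity"].to_numpy(float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < 3:
        raise ValueError(
            "rank-deficient design: gc_percent and relative_length are collinear"
        )
    model = sm.OLS(y, sm.add_constant(X)).fit()
    sx = X.std(axis=0, ddof=1)
    sy = y.std(ddof=1)
    if sy == 0:
        std_gc = std_len = 0.0
    else:
        std_gc = model.params[1] * sx[0] / sy
        std_len = model.params[2] * sx[1] / sy
    return RegressionFit(
        intercept=float(model.params[0]),
        coef_gc=float(model.params[1]),
        coef_len=float(model.params[2]),
        standardized_coef_gc=float(std_gc),
        standardized_coef_len=float(std_len),
        se_gc=float(model.bse[1]),
        se_len=float(model.bse[2]),
        p_gc=float(model.pvalues[1]),
        p_len=float(model.pvalues[2]),
        r_squared=float(model.rsquared) if sy > 0 else 0.0,
        n=n,
    )


def gc_identity_correlation(table: pd.DataFrame) -> dict:
    """Pearson r and Spearman rho between gene %GC and homolog identity."""
    x = table["gc_percent"].to_numpy(float)
    y = table["identity"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 genes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in gc or identity")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return {
        "pearson_r": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman_rho": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
        "n": int(len(x)),
    }
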