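"""The four reference-gene stability algorithms.

Each algorithm scores every candidate gene on its own scale, but all share
one orientation: lower = more stable.

* geNorm (``genorm``): a gene's M value is the mean standard deviation of
  its pairwise log2 expression ratios with every other candidate, computed
  on linear relative quantities; the least stable gene is iteratively
  removed and M recomputed until two genes remain.
* NormFinder, ungrouped (``normfinder_ungrouped``): model-based; after
  removing gene and sample main effects from log2 quantities, a gene's
  stability is the square root of its own residual-variance estimate.
* BestKeeper (``bestkeeper``): descriptive; a gene's dispersion is the mean
  absolute deviation of its raw Cq around the gene's geometric-mean Cq,
  with CV and correlation-to-index diagnostics.
* Comparative delta-Ct (``comparative_dct``): a gene's score is the mean,
  over partner genes, of the standard deviation of the per-sample Cq
  difference with that partner.

geNorm and NormFinder operate on (log) relative quantities; BestKeeper and
comparative delta-Ct operate on raw Cq, matching the conventions of the
original methods.  All standard deviations use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cq_data import CqTable, to_relative_quantity
from .errors import DataError, DesignError

METHODS = ("genorm", "normfinder", "bestkeeper", "delta_ct")


@dataclass
class StabilityScores:
    """Per-gene stability under one method (lower = more stable)."""

    method: str
    scores: pd.Series
    elimination_order: list[str] | None = None  # geNorm only
    diagnostics: pd.DataFrame | None = None  # BestKeeper only

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(float)
        if (self.scores < -1e-12).any():
            raise DataError(f"{self.method}: negative stability score")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.scores.index, "score": self.scores.values})


def _as_matrix(data: CqTable | pd.DataFrame, min_genes: int, min_samples: int, what: str) -> pd.DataFrame:
    values = data.values if isinstance(data, CqTable) else data
    if values.isna().any().any():
        raise DataError(f"{what}: missing cells; take complete cases first")
    if values.shape[1] < min_genes:
        raise DesignError(f"{what} needs >= {min_genes} genes, got {values.shape[1]}")
    if values.shape[0] < min_samples:
        raise DesignError(f"{what} needs >= {min_samples} samples, got {values.shape[0]}")
    return values


def pairwise_variation(qa: np.ndarray | pd.Series, qb: np.ndarray | pd.Series) -> float:
    """geNorm pairwise variation V: sample SD of log2(qa/qb) across samples."""
    a = np.asarray(qa, dtype=float)
    b = np.asarray(qb, dtype=float)
    if a.shape != b.shape:
        raise DataError(f"quantity vectors differ in length: {a.shape} vs {b.shape}")
    if (a <= 0).any() or (b <= 0).any():
        raise DataError("relative quantities must be positive")
    return float(np.std(np.log2(a / b), ddof=1))


def _genorm_m(logq: pd.DataFrame) -> pd.Series:
    """M value of every gene in the current panel (one geNorm round)."""
    arr = logq.to_numpy()
    genes = logq.columns
    g = len(genes)
    m = np.empty(g)
    for j in range(g):
        diffs = arr[:, [j]] - arr  # log2 ratios with every partner
        sds = np.std(diffs, axis=0, ddof=1)
        m[j] = (sds.sum() - sds[j]) / (g - 1)  # exclude self (SD 0)
    return pd.Series(m, index=genes)


def genorm(quantities: pd.DataFrame) -> StabilityScores:
    """geNorm M values with iterative elimination.

    ``quantities`` is a samples x genes matrix of positive linear relative
    quantities (see :func:`refstab.cq_data.to_relative_quantity`).  Each
    round the gene with the largest M is removed and M recomputed, until two
    genes remain.  A gene's reported score is its M in the round of its
    elimination; the genes alive in the last computed round (the surviving
    pair plus the last eliminated gene) keep that round's M.  Ties are
    broken by panel order.
    """
    q = _as_matrix(quantities, min_genes=3, min_samples=2, what="genorm")
    if (q.to_numpy() <= 0).any():
        raise DataError("genorm: relative quantities must be positive")
    logq = np.log2(q)
    remaining = list(logq.columns)
    scores: dict[str, float] = {}
    eliminated: list[str] = []
    while len(remaining) > 2:
        m = _genorm_m(logq[remaining])
        worst = m.idxmax()
        scores[worst] = float(m[worst])
        if len(remaining) == 3:  # last computed round: survivors keep this M
            for g in remaining:
                scores[g] = float(m[g])
        eliminated.append(worst)
        remaining.remove(worst)
    order = eliminated + remaining
    return StabilityScores(
        method="genorm",
        scores=pd.Series(scores).reindex(logq.columns),
        elimination_order=order,
    )


def normfinder_ungrouped(log_quantities: pd.DataFrame) -> StabilityScores:
    """Ungrouped NormFinder stability rho per gene.

    ``log_quantities`` is a samples x genes matrix of log2 relative
    quantities.  The additive model (gene effect + sample effect) is removed
    by double centering; the per-gene variance estimate applies the
    homoscedastic small-sample correction G / ((G-1)(n-1)) to the sum of the
    gene's squared residuals, and rho is its square root (floored at 0).
    """
    y = _as_matrix(log_quantities, min_genes=3, min_samples=3, what="normfinder")
    arr = y.to_numpy(dtype=float)
    n, g = arr.shape
    resid = arr - arr.mean(axis=0) - arr.mean(axis=1, keepdims=True) + arr.mean()
    ss = (resid**2).sum(axis=0)
    s2 = ss * g / ((g - 1) * (n - 1))
    rho = np.sqrt(np.clip(s2, 0.0, None))
    return StabilityScores(method="normfinder", scores=pd.Series(rho, index=y.columns))


def bestkeeper(table: CqTable | pd.DataFrame, use_sd: bool = False) -> StabilityScores:
    """BestKeeper dispersion per gene, on raw Cq.

    Dispersion is the mean absolute deviation of a gene's Cq around its
    geometric-mean Cq (the original tool's "SD(+/-Cq)" convention); pass
    ``use_sd=True`` for the classical sample SD instead.  Diagnostics carry
    the geometric mean, the coefficient of variation (dispersion as a
    percentage of the geometric mean) and the Pearson correlation of each
    gene's Cq with the BestKeeper index (per-sample geometric mean of all
    genes' Cq).
    """
    cq = _as_matrix(table, min_genes=1, min_samples=2, what="bestkeeper")
    arr = cq.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise DataError("bestkeeper: Cq must be positive (geometric mean undefined)")
    geo = np.exp(np.log(arr).mean(axis=0))
    if use_sd:
        disp = arr.std(axis=0, ddof=1)
    else:
        disp = np.abs(arr - geo).mean(axis=0)
    cv = disp / geo * 100.0
    index = np.exp(np.log(arr).mean(axis=1))  # per-sample BestKeeper index
    r = np.empty(arr.shape[1])
    p = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        if np.std(arr[:, j]) == 0 or np.std(index) == 0:
            r[j], p[j] = np.nan, np.nan
        else:
            r[j], p[j] = sps.pearsonr(arr[:, j], index)
    diagnostics = pd.DataFrame(
        {"geo_mean_cq": geo, "cv_percent": cv, "pearson_r": r, "pearson_p": p},
        index=cq.columns,
    )
    return StabilityScores(
        method="bestkeeper",
        scores=pd.Series(disp, index=cq.columns),
        diagnostics=diagnostics,
    )


def comparative_dct(table: CqTable | pd.DataFrame) -> StabilityScores:
    """Comparative delta-Ct stability, on raw Cq.

    For every gene pair the per-sample Cq difference is formed; a gene's
    score is the mean, over its partners, of the sample SD of those
    differences.  At 100% efficiency this equals the geNorm first-round M.
    """
    cq = _as_matrix(table, min_genes=2, min_samples=2, what="comparative_dct")
    arr = cq.to_numpy(dtype=float)
    g = arr.shape[1]
    scores = np.empty(g)
    for j in range(g):
        diffs = arr[:, [j]] - arr
        sds = np.std(diffs, axis=0, ddof=1)
        scores[j] = (sds.sum() - sds[j]) / (g - 1)
    return pd.Series(scores, index=cq.columns).pipe(
        lambda s: StabilityScores(method="delta_ct", scores=s)
    )


def run_all(
    cq_values: pd.DataFrame,
    efficiency: float = 2.0,
    bestkeeper_sd: bool = False,
) -> dict[str, StabilityScores]:
    """Run all four algorithms on one complete mean-Cq matrix.

    geNorm and NormFinder see relative quantities derived at the given
    amplification efficiency; BestKeeper and comparative delta-Ct see the
    raw Cq values.
    """
    q = to_relative_quantity(cq_values, efficiency)
    return {
        "genorm": genorm(q),
        "normfinder": normfinder_ungrouped(np.log2(q)),
        "bestkeeper": bestkeeper(cq_values, use_sd=bestkeeper_sd),
        "delta_ct": comparative_dct(cq_values),
    }
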