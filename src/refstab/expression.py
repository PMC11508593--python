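"""Relative quantification by the 2^-ddCt method and its statistics.

A target gene's expression in sample i is summarised by
``dCt(i) = Cq_target(i) - mean_ref Cq(i)``, where the reference term is the
arithmetic mean Cq over the chosen reference genes — equivalent, at a
common amplification efficiency, to normalising by the geometric mean of
their linear quantities.  Fold change is then ``2**-(dCt(i) - dCt_cal)``
where ``dCt_cal`` is the mean dCt of a calibrator group (by convention the
intact animals at the earliest age), so the calibrator's geometric-mean
fold change is 1.

Downstream inference follows the conventional qPCR workflow: Tukey-fence
outlier exclusion within each group x age cell, two-way ANOVA (Type-III
sums of squares, sum-to-zero coding) on log2 fold change with a Sidak
correction for the pairwise contrasts, and advisory Shapiro-Wilk / Levene
assumption checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .cq_data import CqTable
from .errors import DataError, DesignError


def delta_ct(
    values: pd.DataFrame | CqTable, target: str, refs: Sequence[str]
) -> pd.Series:
    """Per-sample dCt of ``target`` against the mean Cq of ``refs``."""
    df = values.values if isinstance(values, CqTable) else values
    refs = list(refs)
    if not refs:
        raise DesignError("reference gene set is empty")
    if target in refs:
        raise DesignError(f"target {target!r} cannot be one of its own references")
    missing = [g for g in [target, *refs] if g not in df.columns]
    if missing:
        raise DataError(f"gene(s) not in Cq table: {missing}")
    block = df[[target, *refs]]
    if block.isna().any().any():
        bad = [
            (s, g) for s in block.index for g in block.columns
            if pd.isna(block.at[s, g])
        ]
        raise DataError(f"missing Cq cells for dCt: {bad}")
    return df[target] - df[refs].mean(axis=1)


@dataclass
class FoldChangeTable:
    """Per-sample 2^-ddCt values under a stated reference set and calibrator."""

    target: str
    references: tuple[str, ...]
    calibrator: tuple[str, ...]  # the calibrator sample ids
    data: pd.DataFrame  # index sample_id: delta_ct, delta_delta_ct, fold


def ddct_fold_change(
    delta_cts: pd.Series, calibrator: Sequence[str]
) -> pd.DataFrame:
    """Fold change 2^-ddCt with ddCt anchored to the calibrator-mean dCt."""
    cal = [s for s in calibrator]
    if not cal:
        raise DesignError("calibrator sample set is empty")
    present = [s for s in cal if s in delta_cts.index]
    if not present:
        raise DataError(f"calibrator samples {cal} are disjoint from the data")
    ddct = delta_cts - delta_cts.loc[present].mean()
    return pd.DataFrame(
        {"delta_ct": delta_cts, "delta_delta_ct": ddct, "fold": 2.0 ** (-ddct)}
    )


def fold_changes(
    values: pd.DataFrame | CqTable,
    target: str,
    refs: Sequence[str],
    calibrator: Sequence[str],
) -> FoldChangeTable:
    """Convenience composition of :func:`delta_ct` and :func:`ddct_fold_change`."""
    dct = delta_ct(values, target, refs)
    data = ddct_fold_change(dct, calibrator)
    return FoldChangeTable(
        target=target,
        references=tuple(refs),
        calibrator=tuple(s for s in calibrator if s in dct.index),
        data=data,
    )


@dataclass
class OutlierResult:
    values: pd.Series  # retained values
    flags: pd.Series  # True = outlier
    fences: tuple[float, float] | None


def quartile_outlier_filter(values: pd.Series | np.ndarray, k: float = 1.5) -> OutlierResult:
    """Tukey-fence outlier flagging within one group x age cell.

    Quartiles use linear interpolation of order statistics; values outside
    ``[Q1 - k*IQR, Q3 + k*IQR]`` are flagged.  Cells with fewer than four
    values are passed through unfiltered with a warning.
    """
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    if len(s) < 4:
        warnings.warn(
            f"only {len(s)} value(s): too few for quartile outlier filtering; "
            "returning all values unflagged",
            stacklevel=2,
        )
        return OutlierResult(values=s.copy(), flags=pd.Series(False, index=s.index), fences=None)
    q1, q3 = np.percentile(s.to_numpy(), [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    flags = (s < lo) | (s > hi)
    return OutlierResult(values=s[~flags].copy(), flags=flags, fences=(float(lo), float(hi)))


def _validate_two_factor(df: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> None:
    for col in (value, factor_a, factor_b):
        if col not in df.columns:
            raise DataError(f"column {col!r} not in data")
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise DesignError(f"factor {f!r} has fewer than 2 levels")
    cells = df.groupby([factor_a, factor_b], observed=True)[value].count()
    thin = cells[cells < 2]
    if len(thin):
        raise DataError(
            f"cells with fewer than 2 observations: {list(thin.index)}"
        )


def _fit_two_way(df: pd.DataFrame, value: str, factor_a: str, factor_b: str):
    d = df[[value, factor_a, factor_b]].rename(
        columns={value: "y", factor_a: "fa", factor_b: "fb"}
    )
    d["fa"] = d["fa"].astype(str)
    d["fb"] = d["fb"].astype(str)
    return smf.ols("y ~ C(fa, Sum) * C(fb, Sum)", data=d).fit()


def two_way_anova(
    df: pd.DataFrame,
    value: str = "fold",
    factor_a: str = "group",
    factor_b: str = "age",
) -> pd.DataFrame:
    """Two-way ANOVA with interaction, Type-III sums of squares.

    Type-III with sum-to-zero factor coding keeps each effect's test
    meaningful under the unbalanced cell sizes that outlier exclusion
    produces.  Returns a tidy frame with one row per effect plus residual.
    """
    _validate_two_factor(df, value, factor_a, factor_b)
    model = _fit_two_way(df, value, factor_a, factor_b)
    tab = sm.stats.anova_lm(model, typ=3)
    name_map = {
        "C(fa, Sum)": factor_a,
        "C(fb, Sum)": factor_b,
        "C(fa, Sum):C(fb, Sum)": f"{factor_a}:{factor_b}",
        "Residual": "residual",
    }
    tab = tab.drop(index="Intercept")
    tab.index = [name_map.get(i, i) for i in tab.index]
    out = tab.rename(columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"})
    out.index.name = "effect"
    return out.reset_index()


def sidak_posthoc(p: float | np.ndarray | pd.Series, m: int) -> np.ndarray | float:
    """Sidak family-wise adjustment: ``1 - (1 - p)**m``, clipped to [0, 1]."""
    if m < 1:
        raise DesignError(f"number of comparisons must be >= 1, got {m}")
    arr = np.asarray(p, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise DataError("raw p-values must lie in [0, 1]")
    adj = np.clip(1.0 - (1.0 - arr) ** m, 0.0, 1.0)
    return float(adj) if np.isscalar(p) or np.ndim(p) == 0 else adj


def pairwise_contrasts(
    df: pd.DataFrame,
    value: str = "fold",
    factor_a: str = "group",
    factor_b: str = "age",
) -> pd.DataFrame:
    """Sidak-adjusted pairwise cell contrasts after the two-way model.

    The default family contains every between-``factor_a`` contrast within
    each level of ``factor_b`` and every between-``factor_b`` contrast
    within each level of ``factor_a``.  Each contrast is a t-test on the
    difference of cell means using the pooled residual variance and
    residual degrees of freedom of the full interaction model, and the
    Sidak family size m is the number of contrasts actually computed
    (reported in the output).
    """
    _validate_two_factor(df, value, factor_a, factor_b)
    model = _fit_two_way(df, value, factor_a, factor_b)
    mse = model.mse_resid
    dof = model.df_resid
    cells = df.groupby([factor_a, factor_b], observed=True)[value].agg(["mean", "count"])

    rows = []

    def _contrast(c1: tuple, c2: tuple, label: str) -> None:
        if c1 not in cells.index or c2 not in cells.index:
            return
        m1, n1 = cells.loc[c1]
        m2, n2 = cells.loc[c2]
        se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
        praw = 2.0 * sps.t.sf(abs(t), dof)
        rows.append(
            {
                "contrast": label,
                "estimate": m1 - m2,
                "t": t,
                "df": dof,
                "p_raw": praw,
            }
        )

    a_levels = sorted(df[factor_a].astype(str).unique())
    b_levels = sorted(df[factor_b].astype(str).unique())
    for b in b_levels:
        for i, a1 in enumerate(a_levels):
            for a2 in a_levels[i + 1:]:
                _contrast((a1, b), (a2, b), f"{a1} vs {a2} | {factor_b}={b}")
    for a in a_levels:
        for i, b1 in enumerate(b_levels):
            for b2 in b_levels[i + 1:]:
                _contrast((a, b1), (a, b2), f"{b1} vs {b2} | {factor_a}={a}")
    out = pd.DataFrame(rows)
    if out.empty:
        raise DataError("no computable contrasts (all cells empty?)")
    out["m"] = len(out)
    out["p_sidak"] = sidak_posthoc(out["p_raw"].to_numpy(), len(out))
    return out


@dataclass
class AssumptionReport:
    """Advisory normality / variance-homogeneity diagnostics per cell."""

    shapiro: pd.DataFrame  # cell, n, W, p, status
    levene_stat: float | None
    levene_p: float | None
    n_cells_tested: int


def assumption_checks(
    df: pd.DataFrame,
    value: str = "fold",
    by: Sequence[str] = ("group", "age"),
) -> AssumptionReport:
    """Shapiro-Wilk per cell plus Levene (center=mean) across cells.

    Advisory only: the pipeline reports but does not branch on the outcome.
    Cells with fewer than 3 observations are marked "not evaluated".
    """
    by = list(by)
    rows = []
    cell_values = []
    for key, grp in df.groupby(by, observed=True):
        vals = grp[value].to_numpy(dtype=float)
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        if len(vals) >= 3 and np.ptp(vals) > 0:
            w, p = sps.shapiro(vals)
            rows.append({"cell": label, "n": len(vals), "W": w, "p": p, "status": "evaluated"})
        else:
            rows.append(
                {"cell": label, "n": len(vals), "W": np.nan, "p": np.nan, "status": "not evaluated"}
            )
        if len(vals) >= 2:
            cell_values.append(vals)
    if len(cell_values) >= 2:
        stat, p = sps.levene(*cell_values, center="mean")
        levene_stat, levene_p = float(stat), float(p)
    else:
        levene_stat = levene_p = None
    return AssumptionReport(
        shapiro=pd.DataFrame(rows),
        levene_stat=levene_stat,
        levene_p=levene_p,
        n_cells_tested=len(cell_values),
    )


@dataclass
class ExpressionResult:
    """Full expression analysis of one target under one reference set."""

    fold_table: pd.DataFrame  # sample, group, age, delta_ct, delta_delta_ct, fold, outlier
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    assumptions: AssumptionReport
    target: str
    references: tuple[str, ...]
    calibrator_group: str
    calibrator_age: str
    scale: str  # "log2" or "raw": the scale the ANOVA ran on


def analyze_target(
    values: pd.DataFrame | CqTable,
    annotations: pd.DataFrame,
    target: str,
    refs: Sequence[str],
    calibrator: tuple[str, str] | None = None,
    outlier_k: float = 1.5,
    log2_fold: bool = True,
) -> ExpressionResult:
    """End-to-end relative-expression analysis for one target gene.

    ``calibrator`` is a (group, age) pair; by default the intact group at
    the earliest age present.  Outliers are flagged per group x age cell on
    the fold-change values; ANOVA and contrasts run on retained samples,
    on log2 fold change by default.
    """
    df = values.values if isinstance(values, CqTable) else values
    ann = annotations.loc[[s for s in df.index if s in annotations.index]]
    missing_ann = [s for s in df.index if s not in annotations.index]
    if missing_ann:
        raise DataError(f"samples without annotation: {missing_ann}")
    if calibrator is None:
        ages_present = sorted(ann["age"].unique())
        calibrator = ("intact", ages_present[0])
    cal_group, cal_age = calibrator
    cal_samples = list(ann.index[(ann["group"] == cal_group) & (ann["age"] == cal_age)])
    if not cal_samples:
        raise DesignError(f"calibrator cell ({cal_group}, {cal_age}) contains no samples")

    fct = fold_changes(df, target, refs, cal_samples)
    table = fct.data.join(ann[["group", "age"]])

    flags = pd.Series(False, index=table.index)
    for _, grp in table.groupby(["group", "age"], observed=True):
        if len(grp) < 4:
            flags.loc[grp.index] = False
            continue
        res = quartile_outlier_filter(grp["fold"], k=outlier_k)
        flags.loc[grp.index] = res.flags
    table["outlier"] = flags

    kept = table[~table["outlier"]].copy()
    scale = "log2" if log2_fold else "raw"
    kept["response"] = np.log2(kept["fold"]) if log2_fold else kept["fold"]
    anova = two_way_anova(kept, value="response", factor_a="group", factor_b="age")
    contrasts = pairwise_contrasts(kept, value="response", factor_a="group", factor_b="age")
    assumptions = assumption_checks(kept, value="response", by=("group", "age"))
    return ExpressionResult(
        fold_table=table.reset_index(names="sample_id"),
        anova=anova,
        contrasts=contrasts,
        assumptions=assumptions,
        target=target,
        references=tuple(refs),
        calibrator_group=cal_group,
        calibrator_age=cal_age,
        scale=scale,
    )
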