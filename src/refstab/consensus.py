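"""Consensus ranking of stability methods and the two-stage selection rule.

The four stability algorithms rarely agree exactly, so candidates are
compared on a comprehensive stability index: each method's scores are
converted to ranks (1 = most stable, ties averaged) and the index is the
geometric mean of a gene's four ranks — the RefFinder-style aggregate.

Selection is two-staged.  A screening stage discards genes whose index
exceeds a sufficiency threshold defined as a fraction (default 75%) of the
maximum achievable index, which for G genes is G (a gene ranked last by
every method).  A confirmation stage then requires a gene's index to stay
at or below a cap (default 3) in a minimum number (default 3) of the
analysis subsets — conventionally the three single-age analyses plus the
all-ages analysis of one brain structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stability
from .errors import DataError, DesignError
from .stability import StabilityScores


def rank_scores(scores: StabilityScores | pd.Series) -> pd.Series:
    """Ascending ranks (1 = most stable); ties get the average position."""
    s = scores.scores if isinstance(scores, StabilityScores) else scores
    bad = list(s.index[~np.isfinite(s.astype(float))])
    if bad:
        raise DataError(f"non-finite stability score for gene(s): {bad}")
    return pd.Series(sps.rankdata(s.to_numpy(), method="average"), index=s.index)


@dataclass
class ConsensusRanking:
    """Per-gene ranks under each method plus their geometric mean."""

    ranks: pd.DataFrame  # genes x methods
    index: pd.Series  # comprehensive stability index per gene
    subset: str | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.ranks.copy()
        out["index"] = self.index
        return out.sort_values("index")

    def ordering(self) -> list[str]:
        """Genes from most to least stable by the comprehensive index."""
        return list(self.index.sort_values(kind="stable").index)


def comprehensive_index(
    rankings: Mapping[str, pd.Series],
    subset: str | None = None,
) -> ConsensusRanking:
    """Geometric mean of per-method ranks over a common gene set."""
    if len(rankings) < 2:
        raise DesignError("comprehensive_index needs at least two method rankings")
    methods = list(rankings)
    genes = set(rankings[methods[0]].index)
    for m in methods[1:]:
        other = set(rankings[m].index)
        if other != genes:
            raise DataError(
                f"gene sets differ between methods "
                f"(symmetric difference: {sorted(genes ^ other)})"
            )
    ranks = pd.DataFrame({m: rankings[m] for m in methods})
    index = pd.Series(sps.gmean(ranks.to_numpy(), axis=1), index=ranks.index)
    return ConsensusRanking(ranks=ranks, index=index, subset=subset)


def rank_panel(
    cq_values: pd.DataFrame,
    efficiency: float = 2.0,
    subset: str | None = None,
    bestkeeper_sd: bool = False,
) -> tuple[dict[str, StabilityScores], ConsensusRanking]:
    """Run all four algorithms on a complete Cq matrix and aggregate."""
    scores = stability.run_all(cq_values, efficiency=efficiency, bestkeeper_sd=bestkeeper_sd)
    ranking = comprehensive_index(
        {m: rank_scores(s) for m, s in scores.items()}, subset=subset
    )
    return scores, ranking


def structure_rankings(
    table,
    annotations: pd.DataFrame,
    structure: str,
    ages: Sequence[str] = ("P14", "P21", "P50"),
    genes: Sequence[str] | None = None,
    efficiency: float = 2.0,
) -> dict[str, ConsensusRanking]:
    """Consensus rankings for one structure's standard analysis subsets.

    Runs the four algorithms on each single-age subset and on all ages
    pooled ("all"), restricted to ``genes`` (default: every gene in the
    table).  Samples with missing cells are dropped per subset
    (complete-case).
    """
    from . import cq_data  # local import to avoid cycle at module load

    out: dict[str, ConsensusRanking] = {}
    subsets = [(a, [a]) for a in ages] + [("all", list(ages))]
    for label, age_levels in subsets:
        sub = cq_data.subset(table, annotations, structure=structure, ages=age_levels)
        values = sub.complete_cases()
        if genes is not None:
            missing = [g for g in genes if g not in values.columns]
            if missing:
                raise DataError(f"requested gene(s) absent from table: {missing}")
            values = values[list(genes)]
        _, ranking = rank_panel(values, efficiency=efficiency, subset=f"{structure}:{label}")
        out[label] = ranking
    return out


def sufficiency_threshold(n_genes: int, fraction: float = 0.75) -> float:
    """Screening cutoff: ``fraction`` of the maximum achievable index.

    The comprehensive index of a gene ranked last by every method equals the
    panel size, so the maximum achievable index for ``n_genes`` candidates
    is ``n_genes`` and the cutoff is ``fraction * n_genes`` (6 for the
    canonical 8-gene panel at 75%).
    """
    if n_genes < 2:
        raise DesignError(f"need at least 2 genes, got {n_genes}")
    if not 0 < fraction <= 1:
        raise DesignError(f"fraction must be in (0, 1], got {fraction}")
    return fraction * n_genes


@dataclass
class ScreenResult:
    retained: pd.Series  # gene -> index
    excluded: pd.Series
    threshold: float


def screen_genes(ranking: ConsensusRanking, threshold: float) -> ScreenResult:
    """Exclude genes whose comprehensive index strictly exceeds the cutoff.

    A gene exactly at the threshold survives (boundary kept).
    """
    idx = ranking.index
    mask = idx > threshold
    return ScreenResult(
        retained=idx[~mask].copy(), excluded=idx[mask].copy(), threshold=threshold
    )


@dataclass
class SelectionDecision:
    """Outcome of the index<=cap in >=k-of-m-subsets confirmation rule."""

    indices: pd.DataFrame  # genes x subsets
    n_instances: pd.Series
    verdict: pd.Series  # "stable" | "unstable"
    max_index: float
    min_instances: int

    @property
    def stable_genes(self) -> list[str]:
        return list(self.verdict.index[self.verdict == "stable"])

    def to_frame(self) -> pd.DataFrame:
        out = self.indices.copy()
        out["n_instances"] = self.n_instances
        out["verdict"] = self.verdict
        return out


def select_stable(
    per_subset_indices: Mapping[str, pd.Series],
    max_index: float = 3.0,
    min_instances: int = 3,
) -> SelectionDecision:
    """Call a gene stable when its index is <= ``max_index`` (inclusive)
    in at least ``min_instances`` of the analysis subsets."""
    if len(per_subset_indices) < min_instances:
        raise DesignError(
            f"only {len(per_subset_indices)} analysis subset(s) provided but "
            f"min_instances={min_instances}; the rule cannot be satisfied"
        )
    indices = pd.DataFrame(dict(per_subset_indices))
    if indices.isna().any().any():
        missing = [
            (g, c) for g in indices.index for c in indices.columns
            if pd.isna(indices.at[g, c])
        ]
        raise DataError(f"missing index entries: {missing}")
    n_inst = (indices <= max_index).sum(axis=1)
    verdict = pd.Series(
        np.where(n_inst >= min_instances, "stable", "unstable"), index=indices.index
    )
    return SelectionDecision(
        indices=indices,
        n_instances=n_inst,
        verdict=verdict,
        max_index=max_index,
        min_instances=min_instances,
    )
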