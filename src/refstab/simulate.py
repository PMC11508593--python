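"""Synthetic Cq data with known ground truth.

The generator emulates the statistical structure a reference-gene study
assumes on the log (Cq) scale:

    Cq(g, i, r) = mu_g + L_i + delta(g, age_i) + gamma(g, group_i)
                  + b(g, i) + e(g, i, r)

with a per-sample loading offset ``L_i ~ N(0, tau^2)`` (RNA input and RT
yield, shared by all genes of a sample and cancelled by any ratio-based
statistic), per-gene biological noise ``b ~ N(0, sigma_g^2)``, technical
replicate noise ``e ~ N(0, sigma_rep^2)``, and deterministic age / group
effects in cycles (negative = higher expression).  Every draw is
reproducible from the seed.

Alongside the measurements the generator returns a :class:`SimTruth` with
each gene's true total instability and the target genes' true fold-change
profiles, so stability rankings and fold-change estimates computed
downstream can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError

REFERENCE_PANEL = ("Actb", "Gapdh", "B2m", "Rpl13a", "Ppia", "Hprt1", "Pgk1", "Ywhaz")
DEFAULT_TARGETS = ("S100b",)

DEFAULT_BASELINE_CQ = {
    "Actb": 18.0,
    "Gapdh": 20.0,
    "B2m": 22.0,
    "Rpl13a": 21.0,
    "Ppia": 20.5,
    "Hprt1": 25.0,
    "Pgk1": 23.0,
    "Ywhaz": 24.0,
    "S100b": 26.0,
}


@dataclass
class SimParams:
    """Generative parameters for one structure's Cq dataset.

    Effects are keyed ``(gene, level)`` and expressed in cycles on the Cq
    scale; a negative age effect means the gene is more highly expressed at
    that age.  ``noise_sd`` is per-gene biological (between-animal) SD,
    ``loading_sd`` the shared per-sample offset SD, ``replicate_sd`` the
    technical replicate SD.
    """

    genes: tuple[str, ...] = REFERENCE_PANEL
    targets: tuple[str, ...] = DEFAULT_TARGETS
    baseline_cq: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_CQ))
    noise_sd: Mapping[str, float] | float = 0.25
    loading_sd: float = 0.4
    replicate_sd: float = 0.12
    age_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    group_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0
    groups: tuple[str, ...] = ("intact", "control", "FS")
    ages: tuple[str, ...] = ("P14", "P21", "P50")
    structure: str = "DH"
    n_per_cell: int = 8
    n_replicates: int = 4
    seed: int = 0

    @property
    def all_genes(self) -> tuple[str, ...]:
        return tuple(self.genes) + tuple(self.targets)

    def noise_for(self, gene: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(gene, 0.25))
        return float(self.noise_sd)

    def gene_tags(self) -> dict[str, str]:
        """Classify candidate genes by the effects injected into them."""
        tags = {}
        for g in self.genes:
            has_age = any(k[0] == g and v != 0 for k, v in self.age_effects.items())
            has_group = any(k[0] == g and v != 0 for k, v in self.group_effects.items())
            if has_age:
                tags[g] = "drifting"
            elif has_group:
                tags[g] = "group-responsive"
            else:
                tags[g] = "stable"
        return tags

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise DesignError(f"n_replicates must be >= 2, got {self.n_replicates}")
        if self.n_per_cell < 2:
            raise DesignError(f"n_per_cell must be >= 2, got {self.n_per_cell}")
        for name in ("loading_sd", "replicate_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.outlier_fraction <= 1:
            raise DesignError(
                f"outlier_fraction must be in [0, 1], got {self.outlier_fraction}"
            )
        if self.outlier_scale < 1:
            raise DesignError(f"outlier_scale must be >= 1, got {self.outlier_scale}")
        for g in self.all_genes:
            if self.noise_for(g) < 0:
                raise DesignError(f"noise_sd for {g} must be >= 0")
            if g not in self.baseline_cq:
                raise DesignError(f"baseline_cq missing gene {g!r}")
        for (g, level), _ in self.age_effects.items():
            if g not in self.all_genes or level not in self.ages:
                raise DesignError(f"age_effects key ({g!r}, {level!r}) outside the design")
        for (g, level), _ in self.group_effects.items():
            if g not in self.all_genes or level not in self.groups:
                raise DesignError(f"group_effects key ({g!r}, {level!r}) outside the design")
        if len(self.groups) < 1 or len(self.ages) < 1:
            raise DesignError("groups and ages must be non-empty")


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``total_instability`` combines (in quadrature) a gene's biological SD
    with the design-level SD of its injected age/group effects, so it
    orders genes the way an ideal stability analysis of the full design
    should.  ``target_fold`` maps each target gene to its true fold change
    per (group, age) cell relative to the calibrator cell
    (first group, first age).
    """

    total_instability: dict[str, float]
    target_fold: dict[str, dict[str, float]]  # gene -> "group/age" -> fold
    gene_tags: dict[str, str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


def _effect(params: SimParams, gene: str, group: str, age: str) -> float:
    return params.age_effects.get((gene, age), 0.0) + params.group_effects.get(
        (gene, group), 0.0
    )


def _truth(params: SimParams) -> SimTruth:
    cells = [(gr, a) for gr in params.groups for a in params.ages]
    total = {}
    for g in params.genes:
        effects = np.array([_effect(params, g, gr, a) for gr, a in cells])
        total[g] = float(np.sqrt(params.noise_for(g) ** 2 + effects.var()))
    cal = cells[0]
    target_fold = {}
    for t in params.targets:
        base = _effect(params, t, *cal)
        target_fold[t] = {
            f"{gr}/{a}": float(2.0 ** -(_effect(params, t, gr, a) - base))
            for gr, a in cells
        }
    return SimTruth(
        total_instability=total,
        target_fold=target_fold,
        gene_tags=params.gene_tags(),
        seed=params.seed,
    )


def simulate_cq(params: SimParams) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw one dataset: long replicate measurements, annotations, truth.

    Sample ids encode structure, group, age and animal index.  The same
    params (including seed) always give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    sample_ids, sample_group, sample_age = [], [], []
    for gr in params.groups:
        for a in params.ages:
            for k in range(params.n_per_cell):
                sample_ids.append(f"{params.structure}_{gr}_{a}_{k + 1:03d}")
                sample_group.append(gr)
                sample_age.append(a)
    n = len(sample_ids)
    genes = params.all_genes
    g = len(genes)
    r = params.n_replicates

    loading = rng.normal(0.0, params.loading_sd, size=n)
    bio = np.column_stack(
        [rng.normal(0.0, params.noise_for(gene), size=n) for gene in genes]
    )
    if params.outlier_fraction > 0:
        # heavy-tailed contamination: a fraction of animal x gene values has
        # its biological deviation inflated, producing quartile-fence outliers
        hit = rng.random(size=bio.shape) < params.outlier_fraction
        bio = np.where(hit, bio * params.outlier_scale, bio)
    tech = rng.normal(0.0, params.replicate_sd, size=(n, g, r))
    effects = np.array(
        [
            [_effect(params, gene, sample_group[i], sample_age[i]) for gene in genes]
            for i in range(n)
        ]
    )
    mu = np.array([params.baseline_cq[gene] for gene in genes])
    cq = mu[None, :, None] + loading[:, None, None] + (effects + bio)[:, :, None] + tech

    long = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, g * r),
            "gene": np.tile(np.repeat(genes, r), n),
            "replicate": np.tile(np.arange(1, r + 1), n * g),
            "cq": cq.ravel(),
        }
    )
    annotations = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": sample_group,
            "age": sample_age,
            "structure": params.structure,
        }
    ).set_index("sample_id")
    return long, annotations, _truth(params)


def developmental_scenario(
    n_per_cell: int = 8,
    seed: int = 0,
    target_step_fold: float = 2.0,
    drift_cycles: float = 1.0,
    structure: str = "DH",
) -> SimParams:
    """A named scenario mirroring the qualitative findings such a study reports.

    Five candidates are stable; two (Actb, Ywhaz) drift with age — they
    carry a monotone age trend of ``drift_cycles`` cycles by the oldest age
    and, as developmentally regulated genes typically do, elevated
    between-animal noise; one (B2m) responds to the seizure treatment.  The
    target (S100b) steps up ``target_step_fold``-fold from P21 onward in
    every group.
    """
    if n_per_cell < 2:
        raise DesignError(f"n_per_cell must be >= 2, got {n_per_cell}")
    step_cycles = -float(np.log2(target_step_fold))
    noise = {g: 0.25 for g in REFERENCE_PANEL}
    noise["Actb"] = 0.7
    noise["Ywhaz"] = 0.7
    noise["B2m"] = 0.45
    noise["S100b"] = 0.3
    return SimParams(
        noise_sd=noise,
        age_effects={
            ("Actb", "P21"): -drift_cycles / 2,
            ("Actb", "P50"): -drift_cycles,
            ("Ywhaz", "P21"): drift_cycles / 2,
            ("Ywhaz", "P50"): drift_cycles,
            ("S100b", "P21"): step_cycles,
            ("S100b", "P50"): step_cycles,
        },
        group_effects={("B2m", "FS"): 0.8},
        n_per_cell=n_per_cell,
        structure=structure,
        seed=seed,
    )


def graded_noise_panel(
    n_samples: int = 100,
    seed: int = 0,
    sd_range: tuple[float, float] = (0.1, 0.8),
) -> SimParams:
    """Eight candidates with evenly graded biological noise, no effects.

    A single-group, single-age design for parameter-recovery checks: the
    true stability ordering is exactly the noise ordering.
    """
    sds = np.linspace(sd_range[0], sd_range[1], len(REFERENCE_PANEL))
    noise = {g: float(s) for g, s in zip(REFERENCE_PANEL, sds)}
    noise["S100b"] = 0.3
    return SimParams(
        noise_sd=noise,
        groups=("intact",),
        ages=("P14",),
        n_per_cell=n_samples,
        seed=seed,
    )


def write_dataset(
    measurements: pd.DataFrame,
    annotations: pd.DataFrame,
    truth: SimTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write measurements/annotations CSV and truth JSON; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out / "measurements.csv",
        "annotations": out / "annotations.csv",
        "truth": out / "truth.json",
    }
    measurements.to_csv(paths["measurements"], index=False, float_format="%.4f")
    annotations.reset_index().to_csv(paths["annotations"], index=False)
    truth.to_json(paths["truth"])
    return paths
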