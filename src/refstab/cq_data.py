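"""Reading, validation, QC filtering and reshaping of RT-qPCR Cq data.

The quantification cycle (Cq) is the PCR cycle at which a reaction's
fluorescence crosses the detection threshold; lower Cq means more starting
template.  Reactions are run in technical replicates (quadruplicates by
default in the designs this package targets), and a (sample, gene) cell is
only trusted when its replicates agree: cells whose replicate standard
deviation exceeds a configurable cutoff (0.35 cycles by default) are
excluded before any stability or expression analysis.

The module converts long-format replicate tables into a rectangular
samples x genes matrix of mean Cq (:class:`CqTable`), keeps per-cell QC
provenance, and provides the linear-scale relative-quantity transform used
by geNorm-style stability analysis.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DesignError

#: Plausible Cq range; values outside trigger a warning, not an error.
CQ_PLAUSIBLE_RANGE = (5.0, 45.0)

#: Default replicate-SD quality cutoff, in cycles.
DEFAULT_MAX_SD = 0.35

REQUIRED_COLUMNS = ("sample_id", "gene", "replicate", "cq")
ANNOTATION_COLUMNS = ("sample_id", "group", "age", "structure")

DEFAULT_GROUPS = ("intact", "control", "FS")
DEFAULT_AGES = ("P14", "P21", "P50")
DEFAULT_STRUCTURES = ("DH", "VH", "TC", "mPFC")


@dataclass(frozen=True)
class CqMeasurement:
    """A single technical-replicate Cq reading."""

    sample_id: str
    gene: str
    replicate_index: int
    cq: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.cq) or self.cq <= 0:
            raise DataError(
                f"cq must be finite and > 0, got {self.cq!r} "
                f"for ({self.sample_id}, {self.gene}, rep {self.replicate_index})"
            )
        if self.replicate_index < 1:
            raise DataError(
                f"replicate_index must be a positive integer, got {self.replicate_index!r}"
            )
        lo, hi = CQ_PLAUSIBLE_RANGE
        if not lo <= self.cq <= hi:
            warnings.warn(
                f"Cq {self.cq} for ({self.sample_id}, {self.gene}) is outside "
                f"the plausible range [{lo}, {hi}]",
                stacklevel=2,
            )


@dataclass
class ParseReport:
    """Row-level outcome of parsing a measurement file."""

    n_rows: int = 0
    n_parsed: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _sniff_delimiter(first_line: str) -> str:
    """Choose between comma and tab based on the header line."""
    if first_line.count("\t") > first_line.count(","):
        return "\t"
    return ","


def _normalise_header(names: Sequence[str], required: Sequence[str], path: Path) -> dict[str, int]:
    lowered = [n.strip().lower() for n in names]
    mapping: dict[str, int] = {}
    for col in required:
        if col not in lowered:
            raise DataError(f"{path}: missing required column '{col}' (found {names})")
        mapping[col] = lowered.index(col)
    return mapping


def read_measurements(path: str | Path) -> tuple[list[CqMeasurement], ParseReport]:
    """Parse a long-format replicate file into validated measurements.

    The file must have header columns ``sample_id, gene, replicate, cq``
    (any order, case-insensitive; comma or tab delimited).  Rows with a
    non-numeric or non-positive Cq are rejected and listed in the returned
    :class:`ParseReport` with their line numbers.  Duplicate
    ``(sample_id, gene, replicate)`` keys are a hard error.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise DataError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        cols = _normalise_header(header, REQUIRED_COLUMNS, path)

        report = ParseReport()
        measurements: list[CqMeasurement] = []
        seen: dict[tuple[str, str, int], int] = {}
        duplicates: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            report.n_rows += 1
            try:
                sample_id = row[cols["sample_id"]].strip()
                gene = row[cols["gene"]].strip()
                rep_raw = row[cols["replicate"]].strip()
                cq_raw = row[cols["cq"]].strip()
            except IndexError:
                report.rejected.append((lineno, "too few fields"))
                continue
            try:
                replicate = int(rep_raw)
            except ValueError:
                report.rejected.append((lineno, f"non-integer replicate {rep_raw!r}"))
                continue
            try:
                cq = float(cq_raw)
            except ValueError:
                report.rejected.append((lineno, f"non-numeric cq {cq_raw!r}"))
                continue
            try:
                m = CqMeasurement(sample_id, gene, replicate, cq)
            except DataError as exc:
                report.rejected.append((lineno, str(exc)))
                continue
            key = (sample_id, gene, replicate)
            if key in seen:
                duplicates.append(f"line {lineno}: {key} first seen on line {seen[key]}")
            else:
                seen[key] = lineno
                measurements.append(m)
                report.n_parsed += 1
        if duplicates:
            raise DataError(
                f"{path}: duplicate (sample_id, gene, replicate) keys:\n  "
                + "\n  ".join(duplicates)
            )
    return measurements, report


def read_annotations(
    path: str | Path,
    groups: Sequence[str] = DEFAULT_GROUPS,
    ages: Sequence[str] = DEFAULT_AGES,
    structures: Sequence[str] = DEFAULT_STRUCTURES,
) -> pd.DataFrame:
    """Read the sample-annotation table and validate factor vocabularies.

    Returns a DataFrame indexed by ``sample_id`` with columns
    ``group, age, structure``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise DataError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delim)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column '{col}'")
    df = df[list(ANNOTATION_COLUMNS)].astype(str)
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise DataError(f"{path}: duplicate sample_id annotation rows: {sorted(set(dup))}")
    for col, vocab in (("group", groups), ("age", ages), ("structure", structures)):
        bad = sorted(set(df[col]) - set(vocab))
        if bad:
            raise DataError(
                f"{path}: column '{col}' has labels {bad} outside the vocabulary {tuple(vocab)}"
            )
    return df.set_index("sample_id")


def measurements_to_frame(measurements: Iterable[CqMeasurement] | pd.DataFrame) -> pd.DataFrame:
    """Coerce measurements to a long DataFrame (sample_id, gene, replicate, cq)."""
    if isinstance(measurements, pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in measurements.columns]
        if missing:
            raise DataError(f"measurement frame missing columns {missing}")
        return measurements[list(REQUIRED_COLUMNS)].copy()
    rows = [(m.sample_id, m.gene, m.replicate_index, m.cq) for m in measurements]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


@dataclass
class CqTable:
    """Per-sample x gene mean-Cq matrix with replicate QC provenance.

    ``values`` holds the arithmetic mean Cq of the retained replicates; cells
    that failed QC are NaN.  ``replicate_count`` and ``replicate_sd`` cover
    every observed cell, retained or not.  ``excluded`` lists the failing
    cells with their SD and the reason.
    """

    values: pd.DataFrame
    replicate_count: pd.DataFrame
    replicate_sd: pd.DataFrame
    excluded: pd.DataFrame
    max_sd: float = DEFAULT_MAX_SD

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def excluded_samples(self) -> list[str]:
        """Samples with at least one excluded cell (the per-sample QC view)."""
        return sorted(set(self.excluded["sample_id"]))

    def qc_report(self) -> pd.DataFrame:
        """One row per observed cell: n_replicates, sd, status, reason."""
        rows = []
        excl = {
            (r.sample_id, r.gene): r.reason
            for r in self.excluded.itertuples(index=False)
        }
        for sample in self.values.index:
            for gene in self.values.columns:
                n = self.replicate_count.at[sample, gene]
                if pd.isna(n):
                    continue
                reason = excl.get((sample, gene), "")
                rows.append(
                    {
                        "sample_id": sample,
                        "gene": gene,
                        "n_replicates": int(n),
                        "sd": self.replicate_sd.at[sample, gene],
                        "status": "excluded" if reason else "retained",
                        "reason": reason,
                    }
                )
        return pd.DataFrame(rows)

    def complete_cases(self) -> pd.DataFrame:
        """Mean-Cq matrix restricted to samples with no missing gene.

        Stability algorithms need a rectangular, complete matrix; samples
        that lost any cell to replicate QC are dropped with a warning.
        """
        mask = self.values.notna().all(axis=1)
        if not mask.all():
            dropped = list(self.values.index[~mask])
            warnings.warn(
                f"dropping {len(dropped)} sample(s) with missing cells "
                f"(complete-case analysis): {dropped}",
                stacklevel=2,
            )
        return self.values.loc[mask].copy()

    def write(self, path: str | Path, qc_path: str | Path | None = None) -> None:
        """Write the collapsed matrix (and optionally the QC report) as TSV."""
        self.values.round(4).to_csv(path, sep="\t", index_label="sample_id")
        if qc_path is not None:
            self.qc_report().round({"sd": 4}).to_csv(qc_path, sep="\t", index=False)


def collapse_replicates(
    measurements: Iterable[CqMeasurement] | pd.DataFrame,
    max_sd: float = DEFAULT_MAX_SD,
) -> CqTable:
    """Collapse technical replicates to per-cell mean Cq with QC filtering.

    A cell is retained when it has at least two replicates and their sample
    standard deviation (n-1 denominator) does not exceed ``max_sd`` cycles.
    Exclusion is per (sample, gene) cell, not per sample: one failed assay
    does not discard the sample's other genes.  Both views are available on
    the returned table (``excluded`` and ``excluded_samples``).
    """
    if max_sd <= 0:
        raise DesignError(f"max_sd must be positive, got {max_sd}")
    long = measurements_to_frame(measurements)
    if long.empty:
        raise DataError("no measurements to collapse")
    grouped = long.groupby(["sample_id", "gene"], sort=True)["cq"]
    stats = grouped.agg(n="count", mean="mean", sd="std").reset_index()  # std: ddof=1
    # a single replicate yields NaN sd; treat separately below
    insufficient = stats["n"] < 2
    noisy = (~insufficient) & (stats["sd"] > max_sd)
    stats["status"] = np.where(insufficient | noisy, "excluded", "retained")
    stats["reason"] = ""
    stats.loc[insufficient, "reason"] = "insufficient replicates"
    stats.loc[noisy, "reason"] = f"replicate SD exceeds {max_sd}"

    retained = stats[stats["status"] == "retained"]
    values = retained.pivot(index="sample_id", columns="gene", values="mean")
    # keep full sample/gene axes so provenance frames align
    all_samples = sorted(long["sample_id"].unique())
    all_genes = sorted(long["gene"].unique())
    values = values.reindex(index=all_samples, columns=all_genes)
    counts = stats.pivot(index="sample_id", columns="gene", values="n").reindex(
        index=all_samples, columns=all_genes
    )
    sds = stats.pivot(index="sample_id", columns="gene", values="sd").reindex(
        index=all_samples, columns=all_genes
    )
    excluded = stats.loc[
        stats["status"] == "excluded", ["sample_id", "gene", "n", "sd", "reason"]
    ].rename(columns={"n": "n_replicates"})
    values.columns.name = None
    counts.columns.name = None
    sds.columns.name = None
    return CqTable(
        values=values,
        replicate_count=counts,
        replicate_sd=sds,
        excluded=excluded.reset_index(drop=True),
        max_sd=max_sd,
    )


def subset(
    table: CqTable,
    annotations: pd.DataFrame,
    structure: str | None = None,
    ages: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> CqTable:
    """Restrict a CqTable to samples matching the design filters.

    ``ages``/``groups`` are subsets of factor levels; ``None`` keeps all
    levels.  Requesting a level absent from the design is an error, as is a
    filter combination that matches no sample.
    """
    ann = annotations
    mask = pd.Series(True, index=ann.index)
    for name, requested, col in (
        ("structure", None if structure is None else [structure], "structure"),
        ("ages", ages, "age"),
        ("groups", groups, "group"),
    ):
        if requested is None:
            continue
        available = set(ann[col])
        missing = sorted(set(requested) - available)
        if missing:
            raise DesignError(
                f"filter '{name}': level(s) {missing} not present in the design "
                f"(available: {sorted(available)})"
            )
        mask &= ann[col].isin(requested)
    keep = [s for s in table.samples if s in ann.index and mask.get(s, False)]
    unannotated = [s for s in table.samples if s not in ann.index]
    if unannotated:
        raise DataError(f"samples without annotation: {unannotated}")
    if not keep:
        raise DesignError(
            f"empty subset for structure={structure!r}, ages={ages!r}, groups={groups!r}"
        )
    values = table.values.loc[keep]
    incomplete = [g for g in values.columns if values[g].isna().any()]
    if incomplete:
        warnings.warn(
            f"genes with missing cells in subset: {incomplete} "
            "(complete-case handling will drop affected samples)",
            stacklevel=2,
        )
    excl = table.excluded[table.excluded["sample_id"].isin(keep)].reset_index(drop=True)
    return CqTable(
        values=values,
        replicate_count=table.replicate_count.loc[keep],
        replicate_sd=table.replicate_sd.loc[keep],
        excluded=excl,
        max_sd=table.max_sd,
    )


def to_relative_quantity(
    table: CqTable | pd.DataFrame,
    efficiency: float | Mapping[str, float] = 2.0,
) -> pd.DataFrame:
    """Convert mean Cq to linear-scale relative quantities.

    For gene g and sample i, ``q(g, i) = E_g ** (min_i Cq(g) - Cq(g, i))``
    where ``E_g`` is the amplification factor per cycle (2.0 = perfect
    doubling).  Each gene's best-expressed sample gets quantity 1.  Missing
    cells are an error: callers should take complete cases first.
    """
    values = table.values if isinstance(table, CqTable) else table
    if values.isna().any().any():
        bad = [
            (s, g)
            for s in values.index
            for g in values.columns
            if pd.isna(values.at[s, g])
        ]
        raise DataError(f"missing Cq cells: {bad}")
    if isinstance(efficiency, Mapping):
        eff = pd.Series({g: float(efficiency[g]) for g in values.columns})
    else:
        eff = pd.Series(float(efficiency), index=values.columns)
    if (eff <= 1.0).any():
        raise DesignError("amplification efficiency must exceed 1.0 (factor per cycle)")
    return eff ** (values.min(axis=0) - values)
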