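"""Cohort data model, TSV readers/writers, QC and CHIP-threshold filters.

The reproducible input boundary is a flat tab-delimited table with one row
per participant x variant x timepoint::

    participant_id  variant_id  gene  protein_change  consequence
    age_years  depth  alt_reads  [unique_alt_reads  gnomad_p  gene_category  cosmic]

VAFs are always recomputed as ``alt_reads / depth`` and never trusted from
the input.  ``recurrent`` marks a variant_id observed in more than one
participant of the loaded cohort (it selects the overdispersed artifact
model downstream).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimepointObs",
    "VariantAnnotation",
    "Trajectory",
    "Cohort",
    "QCRules",
    "SchemaError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "write_results",
    "qc_filter",
    "chip_threshold_filter",
    "vaf_gradient",
]

REQUIRED_COLUMNS = [
    "participant_id", "variant_id", "gene", "protein_change",
    "consequence", "age_years", "depth", "alt_reads",
]
OPTIONAL_COLUMNS = ["unique_alt_reads", "gnomad_p", "gene_category", "cosmic"]

CONSEQUENCES = {"missense", "nonsense", "frameshift", "splice", "synonymous", "other"}


class SchemaError(ValueError):
    """Input table is missing a required column."""


class ValidationError(ValueError):
    """A row or trajectory violates a data invariant."""


class InsufficientDataError(ValueError):
    """An operation needs more timepoints than the trajectory has."""


@dataclass(frozen=True)
class TimepointObs:
    """One sequencing observation of one variant."""

    age: float
    depth: int
    alt_reads: int
    unique_alt_reads: int | None = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth}")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValidationError(
                f"alt_reads={self.alt_reads} outside [0, depth={self.depth}]"
            )

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ValidationError("VAF undefined at depth 0")
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class VariantAnnotation:
    gene: str
    protein_change: str
    consequence: str
    gnomad_p: float | None = None
    cosmic_reported: bool | None = None
    gene_category: str | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"unknown consequence {self.consequence!r}; expected one of {sorted(CONSEQUENCES)}"
            )

    @property
    def is_synonymous(self) -> bool:
        return self.consequence == "synonymous"


@dataclass
class Trajectory:
    """Longitudinal record of one variant in one participant."""

    participant_id: str
    variant_id: str
    annotation: VariantAnnotation
    points: list[TimepointObs]
    recurrent: bool = False

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValidationError("trajectory needs at least one timepoint")
        ages = [p.age for p in self.points]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValidationError(
                f"{self.participant_id}/{self.variant_id}: ages must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def ages(self) -> np.ndarray:
        return np.array([p.age for p in self.points])

    @property
    def depths(self) -> np.ndarray:
        return np.array([p.depth for p in self.points])

    @property
    def alt_reads(self) -> np.ndarray:
        return np.array([p.alt_reads for p in self.points])

    @property
    def vafs(self) -> np.ndarray:
        return self.alt_reads / self.depths

    @property
    def max_vaf(self) -> float:
        return float(self.vafs.max())


@dataclass
class Cohort:
    trajectories: list[Trajectory]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for t in self.trajectories:
            key = (t.participant_id, t.variant_id)
            if key in seen:
                raise ValidationError(f"duplicate trajectory {key}")
            seen.add(key)
        _set_recurrence(self.trajectories)  # keep the flag consistent cohort-wide

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def participants(self) -> dict[str, list[Trajectory]]:
        out: dict[str, list[Trajectory]] = {}
        for t in self.trajectories:
            out.setdefault(t.participant_id, []).append(t)
        return out

    def synonymous(self) -> list[Trajectory]:
        return [t for t in self.trajectories if t.annotation.is_synonymous]


def _set_recurrence(trajectories: list[Trajectory]) -> None:
    carriers: dict[str, set[str]] = {}
    for t in trajectories:
        carriers.setdefault(t.variant_id, set()).add(t.participant_id)
    for t in trajectories:
        t.recurrent = len(carriers[t.variant_id]) > 1


def read_cohort(path, dialect: dict | None = None) -> Cohort:
    """Read a cohort TSV.  ``dialect`` may override ``sep`` (default tab)."""
    sep = (dialect or {}).get("sep", "\t")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    bad = df.index[df["alt_reads"] > df["depth"]]
    if len(bad):
        raise ValidationError(f"alt_reads > depth at input row {bad[0] + 2} (1-based incl. header)")
    dup = df.duplicated(subset=["participant_id", "variant_id", "age_years"])
    if dup.any():
        row = df.index[dup][0]
        raise ValidationError(
            f"duplicate (participant, variant, age) at input row {row + 2}"
        )
    n_zero = int((df["depth"] == 0).sum())
    if n_zero:
        warnings.warn(f"dropping {n_zero} timepoint(s) with depth 0")
        df = df[df["depth"] > 0]

    trajectories = []
    for (pid, vid), grp in df.groupby(["participant_id", "variant_id"], sort=True):
        grp = grp.sort_values("age_years")
        first = grp.iloc[0]
        ann = VariantAnnotation(
            gene=str(first["gene"]),
            protein_change=str(first["protein_change"]),
            consequence=str(first["consequence"]),
            gnomad_p=_opt_float(first.get("gnomad_p")),
            cosmic_reported=_opt_bool(first.get("cosmic")),
            gene_category=_opt_str(first.get("gene_category")),
        )
        points = [
            TimepointObs(
                age=float(r["age_years"]),
                depth=int(r["depth"]),
                alt_reads=int(r["alt_reads"]),
                unique_alt_reads=(
                    int(r["unique_alt_reads"])
                    if "unique_alt_reads" in grp.columns and pd.notna(r["unique_alt_reads"])
                    else None
                ),
            )
            for _, r in grp.iterrows()
        ]
        trajectories.append(Trajectory(str(pid), str(vid), ann, points))
    _set_recurrence(trajectories)
    return Cohort(trajectories, provenance=f"read from {path}")


def _opt_float(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)


def _opt_bool(x):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return bool(x)


def _opt_str(x):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return str(x)


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for t in cohort:
        for p in t.points:
            rows.append({
                "participant_id": t.participant_id,
                "variant_id": t.variant_id,
                "gene": t.annotation.gene,
                "protein_change": t.annotation.protein_change,
                "consequence": t.annotation.consequence,
                "age_years": p.age,
                "depth": p.depth,
                "alt_reads": p.alt_reads,
                "unique_alt_reads": p.unique_alt_reads,
                "gnomad_p": t.annotation.gnomad_p,
                "gene_category": t.annotation.gene_category,
                "cosmic": t.annotation.cosmic_reported,
            })
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS)


def write_cohort(cohort: Cohort, path) -> None:
    cohort_frame(cohort).to_csv(path, sep="\t", index=False)


def write_results(results, path, format: str = "tsv") -> None:
    """Serialize a pipeline product (DataFrame-like or JSON-serializable)."""
    if format == "tsv":
        if isinstance(results, pd.DataFrame):
            df = results
        elif hasattr(results, "to_frame"):
            df = results.to_frame()
        elif isinstance(results, list) and results and hasattr(results[0], "to_record"):
            df = pd.DataFrame([r.to_record() for r in results])
        else:
            raise TypeError(f"cannot write {type(results).__name__} as TSV")
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "json":
        payload = results.to_dict() if hasattr(results, "to_dict") else results
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_json_default)
    else:
        raise ValueError(f"unknown format {format!r}")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


@dataclass(frozen=True)
class QCRules:
    """Pre-modelling quality filters.

    A trajectory is kept if at least one timepoint passes the coverage
    rules (AO >= min_ao and, when the column is present, UAO >= min_uao),
    if its gnomAD under-representation p-value (when present) is <=
    gnomad_alpha, and if it does not look germline: VAF inside
    ``|v - 0.5| <= germline_halfwidth`` or ``v >= 1 - germline_halfwidth``
    at every timepoint.
    """

    min_ao: int = 5
    min_uao: int = 3
    gnomad_alpha: float = 0.05
    germline_halfwidth: float = 0.05


def qc_filter(cohort: Cohort, rules: QCRules | None = None) -> tuple[Cohort, list[dict]]:
    """Apply QC rules; returns the filtered cohort and a rejection log.

    Rules whose input column is absent everywhere are skipped with a
    warning; filters never raise on data content.
    """
    rules = rules or QCRules()
    have_uao = any(p.unique_alt_reads is not None for t in cohort for p in t.points)
    have_gnomad = any(t.annotation.gnomad_p is not None for t in cohort)
    if not have_uao and len(cohort):
        warnings.warn("unique_alt_reads absent: UAO rule skipped")
    if not have_gnomad and len(cohort):
        warnings.warn("gnomad_p absent: gnomAD rule skipped")

    kept, log = [], []
    for t in cohort:
        rule_hit = None
        passes_cov = any(
            p.alt_reads >= rules.min_ao
            and (p.unique_alt_reads is None or not have_uao or p.unique_alt_reads >= rules.min_uao)
            for p in t.points
        )
        if not passes_cov:
            rule_hit = "coverage"
        elif have_gnomad and t.annotation.gnomad_p is not None and t.annotation.gnomad_p > rules.gnomad_alpha:
            rule_hit = "gnomad"
        else:
            v = t.vafs
            germline = np.all(
                (np.abs(v - 0.5) <= rules.germline_halfwidth)
                | (v >= 1.0 - rules.germline_halfwidth)
            )
            if germline:
                rule_hit = "germline"
        if rule_hit is None:
            kept.append(t)
        else:
            log.append({
                "participant_id": t.participant_id,
                "variant_id": t.variant_id,
                "rule": rule_hit,
            })
    return Cohort(kept, provenance=cohort.provenance), log


def chip_threshold_filter(
    cohort: Cohort, vaf_threshold: float = 0.02, min_timepoints: int = 2
) -> list[Trajectory]:
    """Baseline CHIP call: maximum VAF >= threshold at >= min_timepoints waves."""
    if not 0 < vaf_threshold < 1:
        raise ValueError(f"vaf_threshold must be in (0, 1), got {vaf_threshold}")
    return [
        t for t in cohort
        if len(t) >= min_timepoints and t.max_vaf >= vaf_threshold
    ]


def vaf_gradient(trajectory: Trajectory) -> float:
    """First-to-last VAF slope ``(v(t_end) - v(t_0)) / (t_end - t_0)`` per year.

    Positive gradients define "growing" trajectories.
    """
    if len(trajectory) < 2:
        raise InsufficientDataError("vaf_gradient needs at least two timepoints")
    v = trajectory.vafs
    t = trajectory.ages
    return float((v[-1] - v[0]) / (t[-1] - t[0]))
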