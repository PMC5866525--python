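"""Dose-volume evaluation: DVH metrics, constraints, normalization, reports.

Covers the whole scoring side of the comparison study:

* exact (unbinned) cumulative DVH curves;
* dose-to-hottest-volume (e.g. D0.5cc), dose-to-hottest-fraction (e.g.
  D50%), maximum dose and threshold coverage metrics;
* the two-branch plan normalization used before every comparison — a global
  multiplicative dose rescaling until the first constraint is met exactly:
  either the hottest primary OAR reaches 45 Gy to 0.5 cm^3, or the spinal
  cord / kidney limits bind, whichever comes first (i.e. the minimum scale
  over the constraint set);
* per-fraction and aggregate coverage comparison of conventional vs grouped
  plans (fraction-improved percentages and difference statistics).

All metrics are homogeneous of degree 1 in dose, which is what makes the
"whichever came first" normalization a well-defined minimum over scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import EmptyStructureError, StructureMask, StructureSet, mask_volume

REPORT_SCHEMA_VERSION = 1

ConstraintKind = Literal["dose_to_volume_cc", "dose_to_volume_fraction", "max_dose"]


@dataclass(frozen=True)
class ConstraintSpec:
    """One volumetric dose constraint row.

    ``qualifier`` is a volume in cm^3 for ``dose_to_volume_cc``, a fraction
    in (0, 1] for ``dose_to_volume_fraction``, and ``None`` for ``max_dose``.
    ``limit`` is the dose limit in Gy.
    """

    structure: str
    kind: ConstraintKind
    qualifier: float | None
    limit: float

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError("constraint limit must be > 0 Gy")
        if self.kind == "max_dose":
            if self.qualifier is not None:
                raise ValueError("max_dose takes no volume qualifier")
        elif self.kind == "dose_to_volume_cc":
            if self.qualifier is None or self.qualifier <= 0:
                raise ValueError("dose_to_volume_cc needs a volume in cm^3 > 0")
        elif self.kind == "dose_to_volume_fraction":
            if self.qualifier is None or not (0 < self.qualifier <= 1):
                raise ValueError("dose_to_volume_fraction needs a fraction in (0, 1]")
        else:
            raise ValueError(f"unknown constraint kind {self.kind!r}")

    def describe(self) -> str:
        if self.kind == "max_dose":
            return f"{self.structure}: max dose <= {self.limit} Gy"
        if self.kind == "dose_to_volume_cc":
            return f"{self.structure}: D{self.qualifier}cc <= {self.limit} Gy"
        return f"{self.structure}: D{100 * self.qualifier:.0f}% <= {self.limit} Gy"


def pancreatic_constraints() -> list[ConstraintSpec]:
    """The standard pancreatic constraint set used throughout this package.

    Each of the four primary OARs shares the same volumetric constraint —
    less than 0.5 cm^3 receiving 45 Gy. The spinal cord may not reach 40 Gy
    anywhere (a hard maximum) and the paired kidneys (one unioned mask) must
    keep their median dose, D50%, at or below 15 Gy.
    """
    rows = [ConstraintSpec(n, "dose_to_volume_cc", 0.5, 45.0)
            for n in ("stomach", "duodenum", "small_bowel", "large_bowel")]
    rows.append(ConstraintSpec("cord", "max_dose", None, 40.0))
    rows.append(ConstraintSpec("kidneys", "dose_to_volume_fraction", 0.5, 15.0))
    return rows


# ---------------------------------------------------------------------------
# DVH and derived metrics
# ---------------------------------------------------------------------------

@dataclass
class DvhCurve:
    """Exact cumulative DVH: dose levels (descending) vs cumulative volume.

    ``dose`` holds member-voxel doses sorted in descending order;
    ``cumulative_cm3[i]`` is the structure volume receiving at least
    ``dose[i]``. ``cumulative_pct`` is the same as % of structure volume.
    """

    structure: str
    dose: np.ndarray
    cumulative_cm3: np.ndarray
    cumulative_pct: np.ndarray

    @property
    def total_volume_cm3(self) -> float:
        return float(self.cumulative_cm3[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.dose,
                             "volume_cm3": self.cumulative_cm3,
                             "volume_pct": self.cumulative_pct})

    def plot(self, ax=None, **kwargs):
        """Plot volume-% vs dose on a matplotlib axis (created if absent)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.dose, self.cumulative_pct, label=self.structure, **kwargs)
        ax.set_xlabel("Dose (Gy)")
        ax.set_ylabel("Volume (%)")
        return ax


def _member_doses(dose: np.ndarray, mask: StructureMask) -> np.ndarray:
    if mask.is_empty:
        raise EmptyStructureError(
            f"structure {mask.name!r} is empty; DVH metrics are undefined")
    dose = np.asarray(dose)
    if dose.shape != mask.grid.shape:
        raise ValueError("dose field shape does not match the mask grid")
    return dose[mask.voxels].astype(float)


def dvh(dose: np.ndarray, mask: StructureMask) -> DvhCurve:
    """Exact cumulative DVH from sorted member-voxel doses."""
    d = np.sort(_member_doses(dose, mask))[::-1]
    vol = mask.grid.voxel_volume_cm3
    cum = np.arange(1, d.size + 1) * vol
    return DvhCurve(mask.name, d, cum, 100.0 * cum / cum[-1])


def dose_to_hottest_volume(dose: np.ndarray, mask: StructureMask,
                           volume_cm3: float) -> float:
    """Dose D such that exactly ``volume_cm3`` of the structure receives >= D.

    Linear interpolation on the exact DVH between sorted voxel doses; whole
    voxel volumes only (no sub-voxel partials). Volumes below one voxel
    return the maximum dose.
    """
    total = mask_volume(mask)
    if not (0 < volume_cm3 <= total):
        raise ValueError(
            f"volume {volume_cm3} cm^3 outside (0, {total:.3f}] for "
            f"structure {mask.name!r}")
    curve = dvh(dose, mask)
    return float(np.interp(volume_cm3, curve.cumulative_cm3, curve.dose,
                           left=curve.dose[0]))


def dose_to_hottest_fraction(dose: np.ndarray, mask: StructureMask,
                             fraction: float) -> float:
    """As :func:`dose_to_hottest_volume` with volume = fraction x total."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return dose_to_hottest_volume(dose, mask, fraction * mask_volume(mask))


def max_dose(dose: np.ndarray, mask: StructureMask) -> float:
    """Maximum member-voxel dose (Gy)."""
    return float(_member_doses(dose, mask).max())


def coverage_at(dose: np.ndarray, mask: StructureMask,
                threshold_fraction: float, prescription: float) -> float:
    """Percent of the structure receiving >= threshold_fraction x prescription.

    ``threshold_fraction`` 0.95 gives D95 coverage, 1.0 gives D100 coverage.
    """
    if prescription <= 0:
        raise ValueError("prescription must be > 0 Gy")
    d = _member_doses(dose, mask)
    return 100.0 * float(np.count_nonzero(d >= threshold_fraction * prescription)) / d.size


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def _resolve_constraint_mask(structures: StructureSet, name: str) -> StructureMask:
    """Resolve a constraint's structure name, unioning name-prefixed masks
    (e.g. 'kidneys' over 'kidney_left'/'kidney_right') when no exact match."""
    if name in structures:
        return structures[name]
    stem = name.rstrip("s")
    parts = [s for s in structures if s.name.startswith(stem)]
    if not parts:
        raise KeyError(f"no structure matches constraint target {name!r}")
    union = np.zeros(structures.grid.shape, dtype=bool)
    for p in parts:
        union |= p.voxels
    return StructureMask(structures.grid, union, name, parts[0].role)


def evaluate_constraint_metric(dose: np.ndarray, structures: StructureSet,
                               constraint: ConstraintSpec) -> float:
    """The current value (Gy) of a constraint's metric on a dose field."""
    mask = _resolve_constraint_mask(structures, constraint.structure)
    if constraint.kind == "max_dose":
        return max_dose(dose, mask)
    if constraint.kind == "dose_to_volume_cc":
        return dose_to_hottest_volume(dose, mask, constraint.qualifier)
    return dose_to_hottest_fraction(dose, mask, constraint.qualifier)


@dataclass
class NormalizationResult:
    """Outcome of two-branch plan normalization.

    ``scale`` multiplies the whole dose field; ``binding_constraint`` is the
    row met with equality after scaling; ``dose`` is the scaled field.
    """

    scale: float
    binding_constraint: ConstraintSpec
    dose: np.ndarray
    metrics_before: dict[str, float]

    @property
    def binding_description(self) -> str:
        return self.binding_constraint.describe()


def normalize_plan(plan, structures: StructureSet,
                   constraints: Sequence[ConstraintSpec]) -> NormalizationResult:
    """Rescale a plan's dose until the first dose constraint binds exactly.

    The scale is the minimum of limit/metric over all constraints — the only
    global scaling at which one constraint is met with equality and none is
    exceeded. ``plan`` may be a :class:`~oargroup.planning.PlanResults` or a
    raw dose field. Constraints whose metric is zero cannot bind and are
    skipped; if every metric is zero the normalization is undefined.
    """
    dose = np.asarray(getattr(plan, "dose", plan), dtype=float)
    if not constraints:
        raise ValueError("need at least one constraint to normalize against")
    best_scale = np.inf
    binding = None
    metrics: dict[str, float] = {}
    for c in constraints:
        m = evaluate_constraint_metric(dose, structures, c)
        metrics[c.describe()] = m
        if m <= 0:
            continue
        s = c.limit / m
        if s < best_scale:
            best_scale, binding = s, c
    if binding is None:
        raise ValueError("all constraint metrics are zero (e.g. zero dose); "
                         "normalization is undefined")
    return NormalizationResult(scale=float(best_scale), binding_constraint=binding,
                               dose=dose * best_scale, metrics_before=metrics)


# ---------------------------------------------------------------------------
# Plan comparison report
# ---------------------------------------------------------------------------

COVERAGE_METRICS = ("ptv_d95", "ptv_d100", "ptv_opt_d95")


@dataclass
class CoverageReport:
    """Per-fraction and aggregate conventional-vs-grouped coverage comparison.

    ``per_fraction`` has one row per fraction with conventional, grouped and
    difference (grouped - conventional) columns for each of PTV D95,
    PTV D100 and PTV-OPT D95 coverage (in % of structure volume).
    ``aggregate`` reports, per metric, the percentage of fractions improved
    (ties count as not improved) and mean/SD/min/max of the differences.
    Fractions whose PTV-OPT is empty carry NaN for that metric and are
    excluded from its aggregates.
    """

    per_fraction: pd.DataFrame
    aggregate: dict
    prescription: float
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_json(self) -> str:
        payload = {
            "schema_version": self.schema_version,
            "prescription_gy": self.prescription,
            "aggregate": self.aggregate,
            "per_fraction": self.per_fraction.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    @classmethod
    def from_json(cls, text: str) -> "CoverageReport":
        d = json.loads(text)
        return cls(per_fraction=pd.DataFrame(d["per_fraction"]),
                   aggregate=d["aggregate"],
                   prescription=d["prescription_gy"],
                   schema_version=d["schema_version"])

    def to_csv(self, path) -> None:
        self.per_fraction.to_csv(path, index=False)


def _coverage_triplet(dose: np.ndarray, ptv: StructureMask,
                      ptv_opt: StructureMask, prescription: float
                      ) -> dict[str, float]:
    out = {
        "ptv_d95": coverage_at(dose, ptv, 0.95, prescription),
        "ptv_d100": coverage_at(dose, ptv, 1.0, prescription),
    }
    # An empty PTV-OPT (target fully overlapped after margin) is
    # not-applicable, reported as NaN rather than 0.
    out["ptv_opt_d95"] = (np.nan if ptv_opt.is_empty
                          else coverage_at(dose, ptv_opt, 0.95, prescription))
    return out


def compare_plans(plan_pairs: Sequence[tuple], structure_sets: Sequence[StructureSet],
                  prescription: float, ptv_opt_margin: float = 5.0
                  ) -> CoverageReport:
    """Score per-fraction (conventional, grouped) plan pairs on their anatomy.

    ``plan_pairs`` holds per fraction a (conventional, grouped) pair of
    normalized dose fields or PlanResults; ``structure_sets`` the matching
    per-fraction anatomies (PTV-OPT is built here from each fraction's
    anatomy with ``ptv_opt_margin``).
    """
    from .geometry import make_ptv_opt

    if len(plan_pairs) != len(structure_sets):
        raise ValueError(
            f"{len(plan_pairs)} plan pairs but {len(structure_sets)} anatomies")
    if not plan_pairs:
        raise ValueError("need at least one fraction pair")

    rows = []
    for i, ((conv, grp), ss) in enumerate(zip(plan_pairs, structure_sets)):
        ptv = ss.target
        ptv_opt = make_ptv_opt(ptv, ss.primary_oars, ptv_opt_margin)
        conv_dose = np.asarray(getattr(conv, "dose", conv), dtype=float)
        grp_dose = np.asarray(getattr(grp, "dose", grp), dtype=float)
        c = _coverage_triplet(conv_dose, ptv, ptv_opt, prescription)
        g = _coverage_triplet(grp_dose, ptv, ptv_opt, prescription)
        row = {"fraction": i}
        for m in COVERAGE_METRICS:
            row[f"{m}_conventional"] = c[m]
            row[f"{m}_grouped"] = g[m]
            row[f"{m}_diff"] = g[m] - c[m]
        rows.append(row)

    df = pd.DataFrame(rows)
    aggregate: dict = {"n_fractions": len(rows)}
    for m in COVERAGE_METRICS:
        diffs = df[f"{m}_diff"].to_numpy(dtype=float)
        valid = diffs[~np.isnan(diffs)]
        stats = {
            "n_valid": int(valid.size),
            "pct_fractions_improved": (
                100.0 * float(np.count_nonzero(valid > 0)) / valid.size
                if valid.size else np.nan),
            "mean_diff": float(valid.mean()) if valid.size else np.nan,
            "sd_diff": float(valid.std(ddof=1)) if valid.size > 1 else np.nan,
            "min_diff": float(valid.min()) if valid.size else np.nan,
            "max_diff": float(valid.max()) if valid.size else np.nan,
        }
        aggregate[m] = stats
    return CoverageReport(per_fraction=df, aggregate=aggregate,
                          prescription=prescription)
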