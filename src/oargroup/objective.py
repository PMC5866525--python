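"""Plan objective: per-structure penalty costs and their aggregates.

The plan objective is a weighted sum of one-sided power penalties over
structure voxels. For an OAR with parameters theta = {omega, u, T} the cost
only accrues above the dose threshold T:

    f_oar(D) = sum_v  v_vox * omega * max(0, D_v - T)^u

For the target with theta_t = {omega_lt, omega_ut, l_t, u_t, D0, offset} the
cost grows as dose deviates from the pivot P = D0 + offset, with separate
importance/power pairs below and above:

    f_t(D) = sum_v v_vox * [ omega_lt * max(0, P - D_v)^l_t
                           + omega_ut * max(0, D_v - P)^u_t ]

``v_vox`` is the voxel volume in cm^3; aggregation is a volume-weighted SUM,
not a mean — summation is what makes the grouped objective coincide exactly
with the sum of per-organ objectives when the organs are disjoint and share
one parameter set, which is the algebraic point of the grouping
simplification.

Two planning modes share this machinery. Conventional mode binds each
primary OAR to its own parameter triple (k organs -> 3k tunables); grouped
mode binds one triple to the single grouped structure (3 tunables — the
factor-of-four reduction for the four-organ pancreatic case). Remaining
OARs (spinal cord, kidneys) keep individual terms in both modes.

All powers >= 1 keep the objective convex in dose and differentiable except
exactly at the thresholds, where the one-sided derivative 0 is used. Cost at
D = T exactly is 0 (strict excess).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import yaml

from .dose import InfluenceMatrix
from .geometry import EmptyStructureError, StructureMask, StructureSet

SPEC_FORMAT_VERSION = 1


@dataclass(frozen=True)
class OarCostParams:
    """OAR penalty parameters: importance omega, power u, threshold T (Gy)."""

    importance: float
    power: float
    threshold: float

    def __post_init__(self) -> None:
        if self.importance < 0:
            raise ValueError("importance must be >= 0")
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0 Gy")

    @property
    def n_tunable(self) -> int:
        return 3


@dataclass(frozen=True)
class TargetCostParams:
    """Target penalty parameters.

    Lower/upper importances and powers shape the under-/over-dose branches;
    ``prescribed_dose`` is D0 (Gy) and ``offset`` (Gy) shifts the pivot
    P = D0 + offset that separates the branches.
    """

    importance_lower: float
    importance_upper: float
    power_lower: float
    power_upper: float
    prescribed_dose: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.importance_lower < 0 or self.importance_upper < 0:
            raise ValueError("importances must be >= 0")
        if self.power_lower < 1 or self.power_upper < 1:
            raise ValueError("powers must be >= 1")
        if self.prescribed_dose <= 0:
            raise ValueError("prescribed dose D0 must be > 0 Gy")

    @property
    def pivot(self) -> float:
        return self.prescribed_dose + self.offset


Mode = Literal["conventional", "grouped"]
PivotMode = Literal["single", "deadband"]


@dataclass
class ObjectiveSpec:
    """The full weighting-parameter set theta, frozen at simulation.

    In conventional mode ``primary_oar_bindings`` lists one (name, params)
    pair per primary OAR; in grouped mode it holds exactly one pair bound to
    the grouped structure. ``r_oar_bindings`` carries the remaining-OAR terms
    present in both modes. ``pivot_mode`` selects the default single pivot
    P = D0 + offset, or a symmetric dead band [D0 - offset, D0 + offset].
    """

    mode: Mode
    target_binding: tuple[str, TargetCostParams]
    primary_oar_bindings: list[tuple[str, OarCostParams]]
    r_oar_bindings: list[tuple[str, OarCostParams]] = field(default_factory=list)
    pivot_mode: PivotMode = "single"

    def __post_init__(self) -> None:
        if self.mode not in ("conventional", "grouped"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.pivot_mode not in ("single", "deadband"):
            raise ValueError(f"unknown pivot_mode {self.pivot_mode!r}")
        if self.mode == "grouped" and len(self.primary_oar_bindings) != 1:
            raise ValueError("grouped mode binds exactly one (grouped) structure")
        if not self.primary_oar_bindings:
            raise ValueError("need at least one primary-OAR binding")

    @property
    def grouped_structure_name(self) -> str:
        if self.mode != "grouped":
            raise ValueError("not a grouped-mode spec")
        return self.primary_oar_bindings[0][0]

    def n_primary_oar_parameters(self) -> int:
        """Count of tunable primary-OAR weighting values ({omega, u, T} each)."""
        return sum(p.n_tunable for _, p in self.primary_oar_bindings)

    def bound_names(self) -> list[str]:
        return ([self.target_binding[0]]
                + [n for n, _ in self.primary_oar_bindings]
                + [n for n, _ in self.r_oar_bindings])

    def resolve(self, structures: StructureSet) -> None:
        """Raise KeyError naming the first bound structure missing from a set."""
        for name in self.bound_names():
            if name not in structures:
                raise KeyError(
                    f"objective binds structure {name!r} which is missing from "
                    f"anatomy {structures.label!r} (has: {structures.names})")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": SPEC_FORMAT_VERSION,
            "mode": self.mode,
            "pivot_mode": self.pivot_mode,
            "target": {"structure": self.target_binding[0],
                       **asdict(self.target_binding[1])},
            "primary_oars": [{"structure": n, **asdict(p)}
                             for n, p in self.primary_oar_bindings],
            "r_oars": [{"structure": n, **asdict(p)}
                       for n, p in self.r_oar_bindings],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObjectiveSpec":
        def oar(entry: dict) -> tuple[str, OarCostParams]:
            e = dict(entry)
            return e.pop("structure"), OarCostParams(**e)

        t = dict(d["target"])
        tname = t.pop("structure")
        return cls(mode=d["mode"],
                   target_binding=(tname, TargetCostParams(**t)),
                   primary_oar_bindings=[oar(e) for e in d["primary_oars"]],
                   r_oar_bindings=[oar(e) for e in d.get("r_oars", [])],
                   pivot_mode=d.get("pivot_mode", "single"))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ObjectiveSpec":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Cost evaluation
# ---------------------------------------------------------------------------

def _member_doses(dose: np.ndarray, mask: StructureMask) -> np.ndarray:
    if mask.is_empty:
        raise EmptyStructureError(
            f"structure {mask.name!r} is empty; its cost is undefined")
    dose = np.asarray(dose)
    if dose.shape != mask.grid.shape:
        raise ValueError("dose field shape does not match the mask grid")
    return dose[mask.voxels]


def oar_cost(dose: np.ndarray, mask: StructureMask,
             params: OarCostParams) -> float:
    """One-sided overdose penalty for an OAR (unitless, >= 0)."""
    d = _member_doses(dose, mask)
    excess = np.maximum(0.0, d - params.threshold)
    return float(mask.grid.voxel_volume_cm3 * params.importance
                 * np.sum(excess ** params.power))


def target_cost(dose: np.ndarray, mask: StructureMask,
                params: TargetCostParams,
                pivot_mode: PivotMode = "single") -> float:
    """Two-branch deviation penalty for the target (unitless, >= 0)."""
    d = _member_doses(dose, mask)
    if pivot_mode == "single":
        lower_pivot = upper_pivot = params.pivot
    else:  # symmetric dead band around D0
        lower_pivot = params.prescribed_dose - params.offset
        upper_pivot = params.prescribed_dose + params.offset
    under = np.maximum(0.0, lower_pivot - d)
    over = np.maximum(0.0, d - upper_pivot)
    return float(mask.grid.voxel_volume_cm3
                 * (params.importance_lower * np.sum(under ** params.power_lower)
                    + params.importance_upper * np.sum(over ** params.power_upper)))


def total_objective(dose: np.ndarray, spec: ObjectiveSpec,
                    structures: StructureSet) -> float:
    """Total plan objective f_total for either planning mode.

    Conventional: sum of k primary-OAR costs + target cost + l remaining-OAR
    costs. Grouped: single grouped-OAR cost + target cost + remaining-OAR
    costs. In grouped mode the grouped structure must already exist in
    ``structures`` (built by :func:`oargroup.geometry.group_oars` from the
    anatomy being evaluated).
    """
    spec.resolve(structures)
    total = target_cost(dose, structures[spec.target_binding[0]],
                        spec.target_binding[1], spec.pivot_mode)
    for name, params in spec.primary_oar_bindings:
        total += oar_cost(dose, structures[name], params)
    for name, params in spec.r_oar_bindings:
        total += oar_cost(dose, structures[name], params)
    return total


def dose_gradient(dose: np.ndarray, spec: ObjectiveSpec,
                  structures: StructureSet) -> np.ndarray:
    """d f_total / d D per voxel (grid-shaped field).

    At a threshold exactly, the one-sided derivative 0 is used; powers >= 1
    make every branch differentiable away from its threshold.
    """
    spec.resolve(structures)
    grad = np.zeros(structures.grid.shape, dtype=float)
    vol = structures.grid.voxel_volume_cm3

    tname, tp = spec.target_binding
    tmask = structures[tname]
    d = _member_doses(dose, tmask)
    if spec.pivot_mode == "single":
        lower_pivot = upper_pivot = tp.pivot
    else:
        lower_pivot = tp.prescribed_dose - tp.offset
        upper_pivot = tp.prescribed_dose + tp.offset
    under = np.maximum(0.0, lower_pivot - d)
    over = np.maximum(0.0, d - upper_pivot)
    g = (-tp.importance_lower * tp.power_lower * under ** (tp.power_lower - 1.0)
         * (under > 0)
         + tp.importance_upper * tp.power_upper * over ** (tp.power_upper - 1.0)
         * (over > 0))
    grad[tmask.voxels] += vol * g

    for name, params in list(spec.primary_oar_bindings) + list(spec.r_oar_bindings):
        mask = structures[name]
        d = _member_doses(dose, mask)
        excess = np.maximum(0.0, d - params.threshold)
        g = (params.importance * params.power
             * excess ** (params.power - 1.0) * (excess > 0))
        grad[mask.voxels] += vol * g
    return grad


def objective_gradient(weights: np.ndarray, influence: InfluenceMatrix,
                       spec: ObjectiveSpec,
                       structures: StructureSet) -> np.ndarray:
    """Gradient of the total objective with respect to beamlet weights.

    Chain rule through the linear dose map: grad_w = A @ (df/dD) where A is
    the (beamlet x voxel) influence matrix.
    """
    from .dose import compute_dose

    dose = compute_dose(influence, weights)
    dfdD = dose_gradient(dose, spec, structures)
    return np.asarray(influence.entries @ dfdD.ravel())
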