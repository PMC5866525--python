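"""Fluence-map optimization and the daily adaptive re-planning step.

The central objects follow the model/results pattern:
:class:`FluencePlanModel` holds the data of one planning problem — the
influence matrix, the frozen objective parameter set and the anatomy —
and :meth:`FluencePlanModel.fit` runs projected-gradient descent with
Armijo backtracking over nonnegative beamlet weights, returning a
:class:`PlanResults` carrying the optimized weights, the dose field, the
per-iteration objective trace and convergence diagnostics.

Projected gradient with a monotone line search is used deliberately: the
non-increasing objective trace is then a guarantee by construction, which
the adaptive comparison study leans on. The solver is deterministic given
its inputs — initialization is uniform weights scaled so the mean target
dose equals the prescription D0, so there is no seed dependence.

:func:`adapt_plan` implements the daily adaptive step: the objective
parameters chosen at simulation are frozen and re-used at every treatment
fraction, while the anatomy (and, in grouped mode, the grouped-OAR mask,
which is rebuilt fresh from the fraction anatomy) is that day's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .dose import InfluenceMatrix, compute_dose
from .geometry import StructureSet, group_oars, mask_volume
from .objective import ObjectiveSpec, dose_gradient, total_objective


@dataclass(frozen=True)
class FitOptions:
    """Solver options: iteration cap, relative-decrease tolerance, and the
    grouping distance used when a grouped-mode spec must rebuild its mask."""

    max_iterations: int = 500
    tolerance: float = 1e-6
    initial_weights: np.ndarray | None = None
    grouping_distance: float = 30.0


class FluencePlanModel:
    """One fluence-map optimization problem.

    Parameters
    ----------
    influence
        Beamlet-to-voxel dose mapping (shared across modes and fractions so
        that plan comparisons keep the same beam entry and physical setup).
    spec
        The objective parameter set. For a grouped-mode spec whose grouped
        structure is absent from ``structures``, the grouped mask is built
        here from the supplied anatomy — parameters frozen, geometry fresh.
    structures
        The anatomy this plan is optimized against.
    """

    def __init__(self, influence: InfluenceMatrix, spec: ObjectiveSpec,
                 structures: StructureSet,
                 grouping_distance: float = 30.0) -> None:
        if influence.grid != structures.grid:
            raise ValueError("influence matrix and anatomy use different grids")
        self.grouped_mask_provenance: str | None = None
        if (spec.mode == "grouped"
                and spec.grouped_structure_name not in structures):
            grouped = group_oars(structures, distance_limit=grouping_distance,
                                 name=spec.grouped_structure_name)
            structures = structures.with_structure(grouped)
            self.grouped_mask_provenance = structures.label
        spec.resolve(structures)
        self.influence = influence
        self.spec = spec
        self.structures = structures

    # -- objective plumbing -------------------------------------------------

    def _objective(self, dose: np.ndarray) -> float:
        return total_objective(dose, self.spec, self.structures)

    def _gradient(self, dose: np.ndarray) -> np.ndarray:
        dfdD = dose_gradient(dose, self.spec, self.structures)
        return np.asarray(self.influence.entries @ dfdD.ravel())

    def default_initial_weights(self) -> np.ndarray:
        """Uniform weights scaled so the mean target dose equals D0."""
        target = self.structures[self.spec.target_binding[0]]
        ones = np.ones(self.influence.n_beamlets)
        unit_dose = compute_dose(self.influence, ones)
        mean_target = float(unit_dose[target.voxels].mean())
        if mean_target <= 0:
            raise ValueError("beams deposit no dose in the target; "
                             "check beam geometry")
        d0 = self.spec.target_binding[1].prescribed_dose
        return ones * (d0 / mean_target)

    # -- solver --------------------------------------------------------------

    def fit(self, options: FitOptions | None = None, **kwargs: Any
            ) -> "PlanResults":
        """Minimize the objective over beamlet weights >= 0.

        Projected gradient descent with Armijo backtracking; terminates when
        the relative objective decrease drops below ``tolerance`` or at
        ``max_iterations``. Accepts either a :class:`FitOptions` or the same
        fields as keyword arguments.
        """
        if options is None:
            options = FitOptions(**kwargs)
        elif kwargs:
            options = replace(options, **kwargs)

        if options.initial_weights is not None:
            w = np.asarray(options.initial_weights, dtype=float).copy()
            if np.any(w < 0):
                raise ValueError("initial weights must be nonnegative")
        else:
            w = self.default_initial_weights()

        A = self.influence.entries
        dose = compute_dose(self.influence, w)
        f = self._objective(dose)
        if not np.isfinite(f):
            raise ValueError(f"objective is non-finite at the start ({f})")

        trace = [f]
        g = self._gradient(dose)
        step = 1.0 / max(1.0, float(np.abs(g).max()))
        w_prev = g_prev = None
        converged = False
        slow = 0
        it = 0
        for it in range(1, options.max_iterations + 1):
            if w_prev is not None:
                # Barzilai-Borwein spectral step, safeguarded by the Armijo
                # backtracking below so the trace stays monotone.
                dw = w - w_prev
                dg = g - g_prev
                denom = float(dw @ dg)
                if denom > 1e-30:
                    step = float(dw @ dw) / denom
                else:
                    step *= 2.0
            accepted = False
            while step > 1e-18:
                w_new = np.maximum(0.0, w - step * g)
                dose_new = (A.T @ w_new).reshape(self.influence.grid.shape)
                f_new = self._objective(dose_new)
                # Armijo condition for projected gradient
                if f_new <= f - 1e-4 * float(g @ (w - w_new)):
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                converged = True  # no descent direction left at machine scale
                break
            rel_decrease = (f - f_new) / max(abs(f), 1e-30)
            w_prev, g_prev = w, g
            w, dose, f = w_new, dose_new, f_new
            trace.append(f)
            # BB steps make single-iteration decreases oscillate, so demand
            # a run of sub-tolerance decreases before declaring convergence.
            slow = slow + 1 if rel_decrease < options.tolerance else 0
            if slow >= 3:
                converged = True
                break
            g = self._gradient(dose)

        return PlanResults(model=self, weights=w, dose=dose,
                           objective_trace=np.asarray(trace),
                           converged=converged, iterations=it,
                           options=options)


@dataclass
class PlanResults:
    """An optimized plan: weights, dose, objective trace and diagnostics.

    ``dose`` always equals ``compute_dose(influence, weights)``; the
    objective trace is non-increasing by the line-search construction.
    """

    model: FluencePlanModel
    weights: np.ndarray
    dose: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    iterations: int
    options: FitOptions
    metadata: dict = field(default_factory=dict)

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def spec(self) -> ObjectiveSpec:
        return self.model.spec

    @property
    def structures(self) -> StructureSet:
        return self.model.structures

    @property
    def total_beamlet_weight(self) -> float:
        """Sum of beamlet weights — the sandbox proxy for beam-on time."""
        return float(self.weights.sum())

    def refit(self) -> "PlanResults":
        """Re-run the solver warm-started from this plan's weights."""
        return self.model.fit(replace(self.options, initial_weights=self.weights))

    # -- dosimetric views ----------------------------------------------------

    def dvh(self, structure_name: str):
        from .evaluation import dvh
        return dvh(self.dose, self.structures[structure_name])

    def coverage(self, structure_name: str, threshold_fraction: float,
                 prescription: float) -> float:
        from .evaluation import coverage_at
        return coverage_at(self.dose, self.structures[structure_name],
                           threshold_fraction, prescription)

    def normalize(self, constraints):
        from .evaluation import normalize_plan
        return normalize_plan(self, self.structures, constraints)

    def summary(self) -> str:
        """Plain-text summary of the fit and per-structure dose statistics."""
        lines = [
            "Fluence plan optimization results",
            "=" * 48,
            f"mode:             {self.spec.mode}",
            f"anatomy:          {self.structures.label or '(unnamed)'}",
            f"beamlets:         {self.model.influence.n_beamlets}",
            f"iterations:       {self.iterations} "
            f"({'converged' if self.converged else 'iteration cap'})",
            f"objective:        {self.objective:.6g}",
            f"total weight:     {self.total_beamlet_weight:.4g}",
            "",
            f"{'structure':<16}{'role':<14}{'vol cm3':>9}"
            f"{'Dmean':>9}{'Dmax':>9}",
            "-" * 57,
        ]
        for s in self.structures:
            d = self.dose[s.voxels]
            lines.append(
                f"{s.name:<16}{s.role.value:<14}{mask_volume(s):>9.1f}"
                f"{d.mean():>9.2f}{d.max():>9.2f}")
        return "\n".join(lines)


def optimize_fluence(influence: InfluenceMatrix, spec: ObjectiveSpec,
                     structures: StructureSet,
                     options: FitOptions | None = None) -> PlanResults:
    """Functional entry point: build the model and fit it."""
    opts = options or FitOptions()
    model = FluencePlanModel(influence, spec, structures,
                             grouping_distance=opts.grouping_distance)
    return model.fit(opts)


def adapt_plan(simulation_spec: ObjectiveSpec,
               fraction_structures: StructureSet,
               influence: InfluenceMatrix,
               options: FitOptions | None = None) -> PlanResults:
    """Re-optimize on a fraction's anatomy with the frozen simulation spec.

    The weighting parameters are exactly those chosen at simulation; only the
    anatomy is fresh. In grouped mode the grouped-OAR mask is rebuilt from
    the fraction anatomy (never carried over from simulation); the plan's
    metadata records which anatomy the mask came from.
    """
    opts = options or FitOptions()
    if (simulation_spec.mode == "grouped"
            and simulation_spec.grouped_structure_name in fraction_structures):
        raise ValueError(
            "fraction anatomy already contains the grouped structure; "
            "the grouped mask must be rebuilt from the daily anatomy")
    model = FluencePlanModel(influence, simulation_spec, fraction_structures,
                             grouping_distance=opts.grouping_distance)
    results = model.fit(opts)
    results.metadata["adapted"] = True
    results.metadata["anatomy"] = fraction_structures.label
    if simulation_spec.mode == "grouped":
        results.metadata["grouped_mask_from"] = model.grouped_mask_provenance
    return results
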