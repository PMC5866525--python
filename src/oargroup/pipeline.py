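"""End-to-end study orchestration shared by the CLI and scripts.

Implements the full comparison workflow on one synthetic patient: generate
the simulation anatomy, build one influence matrix (both planning modes and
every fraction share the same beam entry and physical setup), optimize the
conventional and grouped simulation plans, then for each treatment fraction
deform the anatomy, re-optimize both modes with the frozen simulation
objectives, normalize each plan to the shared constraint set and score
PTV / PTV-OPT coverage. The result feeds the comparison report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .dose import BeamConfig, InfluenceMatrix, build_influence
from .evaluation import (ConstraintSpec, CoverageReport, compare_plans,
                         normalize_plan, pancreatic_constraints)
from .geometry import Grid
from .planning import FitOptions, adapt_plan, optimize_fluence
from .phantom import (DeformationSpec, PhantomSpec, generate_phantom,
                      make_objective_specs, simulate_fraction)

MODES = ("conventional", "grouped")


@dataclass
class StudyConfig:
    """Everything a full run needs; loadable from a YAML mapping."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    grid_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    ptv_volume_cm3: float = 160.5
    n_fractions: int = 5
    prescription: float = 50.0
    ptv_opt_margin: float = 5.0
    grouping_distance: float = 30.0
    equal_weights: bool = False
    translation_mm: float = 8.0
    volume_change: float = 0.15
    beams: BeamConfig = field(default_factory=BeamConfig)
    fit: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("need at least one fraction")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "beams" in d:
            b = dict(d["beams"])
            if "gantry_angles" in b:
                b["gantry_angles"] = tuple(b["gantry_angles"])
            d["beams"] = BeamConfig(**b)
        if "fit" in d:
            d["fit"] = FitOptions(**d["fit"])
        for key in ("grid_shape", "grid_spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        import yaml

        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.grid_spacing)


@dataclass
class FractionOutcome:
    """One fraction's adapted, normalized plans and their provenance."""

    fraction_seed: int
    structures: "object"
    plans: dict  # mode -> PlanResults
    normalized: dict  # mode -> NormalizationResult


@dataclass
class StudyResult:
    """Everything a full run produced, ready for reporting or saving."""

    config: StudyConfig
    seed: int
    simulation_structures: "object"
    specs: dict  # mode -> ObjectiveSpec
    simulation_plans: dict  # mode -> PlanResults
    fractions: list[FractionOutcome]
    report: CoverageReport
    constraints: list[ConstraintSpec]

    @property
    def simulation_comparability(self) -> dict:
        """Side-by-side simulation-plan summary, incl. total-weight ratio
        (the sandbox proxy for comparable beam-on time; reported, not
        enforced)."""
        conv = self.simulation_plans["conventional"]
        grp = self.simulation_plans["grouped"]
        return {
            "objective": {m: self.simulation_plans[m].objective for m in MODES},
            "iterations": {m: self.simulation_plans[m].iterations for m in MODES},
            "total_beamlet_weight": {m: self.simulation_plans[m].total_beamlet_weight
                                     for m in MODES},
            "weight_ratio_grouped_over_conventional":
                grp.total_beamlet_weight / conv.total_beamlet_weight,
        }


def run_study(seed: int, config: StudyConfig | None = None,
              influence: InfluenceMatrix | None = None) -> StudyResult:
    """Run the full conventional-vs-grouped adaptive study for one patient.

    Deterministic given (seed, config). ``influence`` may be passed in to
    reuse a cached matrix across studies on the same grid and beams.
    """
    config = config or StudyConfig()
    phantom_spec = PhantomSpec(grid=config.grid,
                               ptv_volume_cm3=config.ptv_volume_cm3, seed=seed)
    sim = generate_phantom(phantom_spec)
    if influence is None:
        influence = build_influence(config.grid, config.beams)
    elif influence.grid != config.grid:
        raise ValueError("supplied influence matrix is on a different grid")

    conv_spec, grouped_spec = make_objective_specs(
        sim, prescription=config.prescription,
        grouping_distance=config.grouping_distance,
        equal_weights=config.equal_weights)
    specs = {"conventional": conv_spec, "grouped": grouped_spec}
    fit = dataclasses.replace(config.fit,
                              grouping_distance=config.grouping_distance)

    simulation_plans = {m: optimize_fluence(influence, specs[m], sim, fit)
                        for m in MODES}

    constraints = pancreatic_constraints()
    deform = DeformationSpec(translation_mm=config.translation_mm,
                             volume_change=config.volume_change, seed=seed)
    fractions: list[FractionOutcome] = []
    for k in range(1, config.n_fractions + 1):
        frac = simulate_fraction(sim, deform, fraction_seed=k)
        plans = {m: adapt_plan(specs[m], frac, influence, fit) for m in MODES}
        normalized = {m: normalize_plan(plans[m], frac, constraints)
                      for m in MODES}
        fractions.append(FractionOutcome(k, frac, plans, normalized))

    report = compare_plans(
        [(f.normalized["conventional"].dose, f.normalized["grouped"].dose)
         for f in fractions],
        [f.structures for f in fractions],
        prescription=config.prescription,
        ptv_opt_margin=config.ptv_opt_margin)
    return StudyResult(config, seed, sim, specs, simulation_plans,
                       fractions, report, constraints)


def study_manifest(result: StudyResult) -> dict:
    """Reproducibility manifest: config, seeds, version, key outcomes."""
    from . import __version__

    return {
        "software_version": __version__,
        "seed": result.seed,
        "config": {
            "grid_shape": list(result.config.grid_shape),
            "grid_spacing": list(result.config.grid_spacing),
            "ptv_volume_cm3": result.config.ptv_volume_cm3,
            "n_fractions": result.config.n_fractions,
            "prescription": result.config.prescription,
            "ptv_opt_margin": result.config.ptv_opt_margin,
            "grouping_distance": result.config.grouping_distance,
            "equal_weights": result.config.equal_weights,
            "translation_mm": result.config.translation_mm,
            "volume_change": result.config.volume_change,
            "beams": dataclasses.asdict(result.config.beams),
            "fit": {"max_iterations": result.config.fit.max_iterations,
                    "tolerance": result.config.fit.tolerance},
        },
        "simulation_comparability": result.simulation_comparability,
        "fractions": [
            {"fraction_seed": f.fraction_seed,
             "anatomy": f.structures.label,
             "normalization": {
                 m: {"scale": f.normalized[m].scale,
                     "binding_constraint": f.normalized[m].binding_description}
                 for m in MODES}}
            for f in result.fractions],
    }


def save_study(result: StudyResult, outdir: str | Path,
               save_plans: bool = False) -> None:
    """Write the report (CSV + JSON), manifest and optionally every plan."""
    from .io import save_plan, save_structure_set

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(result.report.to_json())
    result.report.to_csv(outdir / "report.csv")
    (outdir / "manifest.json").write_text(
        json.dumps(study_manifest(result), indent=2, sort_keys=True))
    save_structure_set(result.simulation_structures, outdir / "phantom")
    for m, spec in result.specs.items():
        (outdir / f"objective_{m}.yaml").write_text(spec.to_yaml())
    if save_plans:
        for m in MODES:
            save_plan(result.simulation_plans[m], outdir / "simulation",
                      stem=f"sim_{m}")
        for f in result.fractions:
            fdir = outdir / f"fraction_{f.fraction_seed:02d}"
            save_structure_set(f.structures, fdir / "anatomy")
            for m in MODES:
                save_plan(f.plans[m], fdir, stem=m)
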