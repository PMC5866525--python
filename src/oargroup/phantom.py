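"""Seeded synthetic abdominal anatomy and inter-fraction deformation.

The comparison study this package reproduces ran on clinical pancreatic
anatomy that is not publicly available, so every pipeline stage is exercised
instead on synthetic phantoms that emulate the cohort geometry: one PTV
(by default the cohort-mean 160.5 cm^3, always within the cohort range
57.7-356.3 cm^3) surrounded by four deformable gastrointestinal primary
OARs (stomach, duodenum, small bowel, large bowel), a spinal cord posterior
and paired kidneys posterolateral. Organs are ellipsoids and curved tubes
(capsule chains) rasterized to boolean masks — the simplest geometry that
produces all three regimes the method cares about: OAR overlapping the PTV,
OAR near but outside, and OAR distant.

Inter-fraction anatomical change is modeled as per-organ rigid translation
plus morphological volume scaling (exact voxel-count bookkeeping via the
signed distance transform) plus an optional smooth random displacement
field; the PTV contour is held constant throughout treatment, exactly as in
the clinical workflow being emulated. All three generator operations are
fully deterministic given their seeds.

The module also generates the objective parameter sets for the study:
conventional weighting is distance-informed (importance falls with an
organ's simulation-day distance band from the PTV), mirroring how planners
assign weights largely by proximity — which is precisely the behavior the
mismatch scenario (:func:`scenario_mismatch`) stresses: an organ that is
distant (hence down-weighted) at simulation becomes adjacent to the PTV at
a later fraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (Grid, Role, StructureMask, StructureSet,
                       distance_to_structure)
from .objective import ObjectiveSpec, OarCostParams, TargetCostParams

PTV_VOLUME_RANGE_CM3 = (57.7, 356.3)
DEFAULT_PTV_VOLUME_CM3 = 160.5

PRIMARY_OAR_NAMES = ("stomach", "duodenum", "small_bowel", "large_bowel")


class PhantomGeometryError(ValueError):
    """Raised when an organ rasterizes to an empty mask or leaves the grid."""


# ---------------------------------------------------------------------------
# Organ templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center offset from grid center (mm), radii (mm)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]


@dataclass(frozen=True)
class Tube:
    """Capsule chain: voxels within ``radius`` mm of the polyline ``points``
    (offsets from grid center, mm)."""

    points: tuple[tuple[float, float, float], ...]
    radius: float


@dataclass(frozen=True)
class OrganTemplate:
    name: str
    role: Role
    shapes: tuple = ()


def default_organ_templates() -> dict[str, OrganTemplate]:
    """Abdominal layout emulating a pancreatic-cancer case.

    Axes: x lateral, y anterior(-)/posterior(+), z inferior/superior, all in
    mm relative to the grid center where the PTV sits. The stomach and small
    bowel abut/overlap the PTV, the duodenum hugs its right side, the large
    bowel passes anteriorly at a near-but-outside distance, the cord runs
    posterior and the kidneys sit posterolateral, well clear of the
    gastrointestinal organs.
    """
    return {
        "stomach": OrganTemplate("stomach", Role.PRIMARY_OAR, (
            Ellipsoid((-50.0, -30.0, 15.0), (40.0, 26.0, 30.0)),)),
        "duodenum": OrganTemplate("duodenum", Role.PRIMARY_OAR, (
            Tube(tuple((42.0 * np.cos(p), 42.0 * np.sin(p),
                        -25.0 + 50.0 * (p + np.pi / 3) / (2 * np.pi / 3))
                       for p in np.linspace(-np.pi / 3, np.pi / 3, 7)),
                 10.0),)),
        "small_bowel": OrganTemplate("small_bowel", Role.PRIMARY_OAR, (
            Ellipsoid((10.0, -55.0, -30.0), (45.0, 30.0, 35.0)),)),
        "large_bowel": OrganTemplate("large_bowel", Role.PRIMARY_OAR, (
            Tube(((-80.0, -25.0, -20.0), (-30.0, -33.0, -22.0),
                  (30.0, -28.0, -24.0), (80.0, -15.0, -25.0)), 12.0),)),
        "cord": OrganTemplate("cord", Role.R_OAR, (
            Tube(((0.0, 85.0, -126.0), (0.0, 85.0, 126.0)), 6.0),)),
        "kidneys": OrganTemplate("kidneys", Role.R_OAR, (
            Ellipsoid((-75.0, 55.0, -10.0), (18.0, 22.0, 40.0)),
            Ellipsoid((75.0, 55.0, -10.0), (18.0, 22.0, 40.0)))),
    }


@dataclass
class PhantomSpec:
    """Specification of one synthetic patient.

    ``ptv_volume_cm3`` must lie within the emulated cohort range (57.7 to
    356.3 cm^3) unless ``allow_out_of_range`` is set. ``seed`` drives small
    per-patient jitter of organ positions, sizes and PTV aspect ratio.
    """

    grid: Grid = field(default_factory=lambda: Grid((64, 64, 64), (4.0, 4.0, 4.0)))
    ptv_volume_cm3: float = DEFAULT_PTV_VOLUME_CM3
    organs: dict[str, OrganTemplate] = field(default_factory=default_organ_templates)
    seed: int = 0
    jitter_mm: float = 5.0
    radius_jitter: float = 0.08
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        lo, hi = PTV_VOLUME_RANGE_CM3
        if not self.allow_out_of_range and not (lo <= self.ptv_volume_cm3 <= hi):
            raise ValueError(
                f"requested PTV volume {self.ptv_volume_cm3} cm^3 outside the "
                f"emulated cohort range [{lo}, {hi}] cm^3")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _grid_center(grid: Grid) -> np.ndarray:
    return np.asarray(grid.origin) + 0.5 * np.asarray(grid.extent_mm())


def _rasterize_ellipsoid(grid: Grid, coords: np.ndarray, e: Ellipsoid,
                         shift: np.ndarray, scale: float) -> np.ndarray:
    c = _grid_center(grid) + np.asarray(e.center) + shift
    r = np.asarray(e.radii) * scale
    q = (coords - c) / r
    return (np.einsum("ij,ij->i", q, q) <= 1.0).reshape(grid.shape)

def _rasterize_tube(grid: Grid, coords: np.ndarray, t: Tube,
                    shift: np.ndarray, scale: float) -> np.ndarray:
    center = _grid_center(grid)
    pts = np.asarray(t.points) + center + shift
    r = t.radius * scale
    best = np.full(coords.shape[0], np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d2 = np.sum((coords - a) ** 2, axis=1)
        else:
            s = np.clip((coords - a) @ ab / denom, 0.0, 1.0)
            d2 = np.sum((coords - (a + s[:, None] * ab)) ** 2, axis=1)
        np.minimum(best, d2, out=best)
    return (best <= r * r).reshape(grid.shape)


def _rasterize(grid: Grid, coords: np.ndarray, template: OrganTemplate,
               shift: np.ndarray, scale: float) -> np.ndarray:
    out = np.zeros(grid.shape, dtype=bool)
    for shape in template.shapes:
        if isinstance(shape, Ellipsoid):
            out |= _rasterize_ellipsoid(grid, coords, shape, shift, scale)
        elif isinstance(shape, Tube):
            out |= _rasterize_tube(grid, coords, shape, shift, scale)
        else:
            raise TypeError(f"unknown shape {type(shape).__name__}")
    return out


def generate_phantom(spec: PhantomSpec, label: str | None = None) -> StructureSet:
    """Rasterize a seeded synthetic anatomy to a StructureSet.

    Deterministic for a fixed spec. The PTV is an ellipsoid of the requested
    volume (aspect ratio jittered per seed, analytic volume preserved, so
    the measured voxel volume stays within rasterization error of the
    request). Primary OARs never overlap the cord or kidneys — any such
    voxels are removed from the primary organ.
    """
    rng = np.random.default_rng(np.random.SeedSequence([77001, spec.seed]))
    grid = spec.grid
    coords = grid.voxel_centers()

    # PTV: sphere-equivalent radius from the requested volume, jittered
    # aspect with the product of radii (hence the volume) held fixed.
    r_eq = (3.0 * spec.ptv_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    a, b = rng.uniform(0.92, 1.08, size=2)
    radii = (r_eq * a, r_eq * b, r_eq / (a * b))
    ptv_vox = _rasterize_ellipsoid(grid, coords,
                                   Ellipsoid((0.0, 0.0, 0.0), radii),
                                   np.zeros(3), 1.0)
    structures = [StructureMask(grid, ptv_vox, "ptv", Role.TARGET)]

    masks: dict[str, np.ndarray] = {}
    for name, template in spec.organs.items():
        shift = rng.uniform(-spec.jitter_mm, spec.jitter_mm, size=3)
        scale = 1.0 + rng.uniform(-spec.radius_jitter, spec.radius_jitter)
        vox = _rasterize(grid, coords, template, shift, scale)
        if not vox.any():
            raise PhantomGeometryError(
                f"organ {name!r} rasterized to an empty mask")
        masks[name] = vox

    r_oar_union = np.zeros(grid.shape, dtype=bool)
    for name, template in spec.organs.items():
        if template.role is Role.R_OAR:
            r_oar_union |= masks[name]
    for name, template in spec.organs.items():
        vox = masks[name]
        if template.role is Role.PRIMARY_OAR:
            vox = vox & ~r_oar_union
            if not vox.any():
                raise PhantomGeometryError(
                    f"organ {name!r} vanished after cord/kidney exclusion")
        structures.append(StructureMask(grid, vox, name, template.role))

    return StructureSet(grid, structures,
                        label or f"phantom(seed={spec.seed})")


# ---------------------------------------------------------------------------
# Inter-fraction deformation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganDeformation:
    """Per-organ deformation ranges: translation (mm, per axis, uniform in
    [-t, t]) and relative volume change (uniform in [-v, v], as a fraction)."""

    translation_mm: float = 8.0
    volume_change: float = 0.15

    def __post_init__(self) -> None:
        if self.translation_mm < 0:
            raise ValueError("translation range must be >= 0")
        if not (0 <= self.volume_change <= 0.5):
            raise ValueError("volume change range must be within +/-50%")


@dataclass
class DeformationSpec:
    """Inter-fraction deformation model parameters.

    Primary OARs move and change volume with the default ranges; the kidneys
    translate at half range without volume change and the spinal cord is
    fixed, unless overridden in ``per_organ``. ``warp_amplitude_mm`` > 0 adds
    a smooth random displacement field with correlation length
    ``smoothness_mm`` before the exact volume adjustment.
    """

    translation_mm: float = 8.0
    volume_change: float = 0.15
    smoothness_mm: float = 25.0
    warp_amplitude_mm: float = 0.0
    seed: int = 0
    per_organ: dict[str, OrganDeformation] = field(default_factory=dict)

    def for_organ(self, mask: StructureMask) -> OrganDeformation:
        if mask.name in self.per_organ:
            return self.per_organ[mask.name]
        if mask.role is Role.R_OAR:
            if mask.name == "cord":
                return OrganDeformation(0.0, 0.0)
            return OrganDeformation(self.translation_mm / 2.0, 0.0)
        return OrganDeformation(self.translation_mm, self.volume_change)


def _integer_shift(vox: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    """Shift a boolean field by whole voxels, dropping what leaves the grid."""
    out = np.zeros_like(vox)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift_vox):
        s = int(s)
        n = vox.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src[ax] = slice(0, n - s)
            dst[ax] = slice(s, n)
        else:
            src[ax] = slice(-s, n)
            dst[ax] = slice(0, n + s)
    out[tuple(dst)] = vox[tuple(src)]
    return out


def _smooth_warp(vox: np.ndarray, grid: Grid, rng: np.random.Generator,
                 amplitude_mm: float, smoothness_mm: float) -> np.ndarray:
    """Warp a mask with a divergence-unconstrained smooth random field."""
    sigma_vox = [smoothness_mm / s for s in grid.spacing]
    disp = []
    for ax in range(3):
        f = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma_vox)
        rms = float(np.sqrt(np.mean(f * f)))
        disp.append(f / max(rms, 1e-12) * amplitude_mm / grid.spacing[ax])
    idx = np.indices(grid.shape, dtype=float)
    sample = [idx[ax] + disp[ax] for ax in range(3)]
    return ndimage.map_coordinates(vox.astype(np.uint8), sample, order=0,
                                   mode="constant", cval=0).astype(bool)


def _exact_volume_adjust(vox: np.ndarray, grid: Grid, target_count: int
                         ) -> np.ndarray:
    """Grow/shrink a mask morphologically to an exact voxel count.

    Voxels are ranked by the signed Euclidean distance to the mask boundary
    (negative inside); the ``target_count`` smallest are kept. Ties are
    broken by flat index so the operation is deterministic.
    """
    if target_count <= 0:
        raise PhantomGeometryError("volume adjustment to zero voxels")
    if target_count == int(vox.sum()):
        return vox.copy()
    inside = ndimage.distance_transform_edt(vox, sampling=grid.spacing)
    outside = ndimage.distance_transform_edt(~vox, sampling=grid.spacing)
    signed = (outside - inside).ravel()
    order = np.lexsort((np.arange(signed.size), signed))
    keep = order[:target_count]
    out = np.zeros(signed.size, dtype=bool)
    out[keep] = True
    return out.reshape(vox.shape)


def simulate_fraction(base: StructureSet, deform: DeformationSpec,
                      fraction_seed: int) -> StructureSet:
    """Deform a simulation anatomy into one treatment fraction's anatomy.

    The target mask is copied unchanged (the PTV contour is held constant
    throughout treatment); every OAR is optionally warped, rigidly
    translated (whole voxels) and volume-adjusted to an exactly drawn voxel
    count, then clipped against the cord/kidneys so primary organs never
    overlap them. Deterministic given (deform.seed, fraction_seed).
    """
    grid = base.grid
    new_masks: dict[str, np.ndarray] = {}
    organs = [s for s in base if s.role is not Role.TARGET]
    for oi, s in enumerate(organs):
        rng = np.random.default_rng(
            np.random.SeedSequence([77002, deform.seed, fraction_seed, oi]))
        rules = deform.for_organ(s)
        vox = s.voxels
        if deform.warp_amplitude_mm > 0:
            vox = _smooth_warp(vox, grid, rng, deform.warp_amplitude_mm,
                               deform.smoothness_mm)
        shift_mm = rng.uniform(-rules.translation_mm, rules.translation_mm, 3)
        shift_vox = np.round(shift_mm / np.asarray(grid.spacing)).astype(int)
        vox = _integer_shift(vox, shift_vox)
        if not vox.any():
            raise PhantomGeometryError(
                f"deformation pushed organ {s.name!r} fully off the grid")
        factor = 1.0 + rng.uniform(-rules.volume_change, rules.volume_change)
        target_count = max(1, int(round(s.voxel_count * factor)))
        vox = _exact_volume_adjust(vox, grid, target_count)
        new_masks[s.name] = vox

    r_oar_union = np.zeros(grid.shape, dtype=bool)
    for s in organs:
        if s.role is Role.R_OAR:
            r_oar_union |= new_masks[s.name]

    structures = []
    for s in base:
        if s.role is Role.TARGET:
            structures.append(s.with_voxels(s.voxels.copy()))
            continue
        vox = new_masks[s.name]
        if s.role is Role.PRIMARY_OAR:
            vox = vox & ~r_oar_union
            if not vox.any():
                raise PhantomGeometryError(
                    f"organ {s.name!r} vanished after cord/kidney exclusion")
        structures.append(s.with_voxels(vox))
    return StructureSet(grid, structures,
                        f"{base.label}/fraction(seed={fraction_seed})")


# ---------------------------------------------------------------------------
# Objective parameter generation (distance-informed weighting)
# ---------------------------------------------------------------------------

# Importance bands by an organ's minimum distance to the PTV at simulation:
# abutting/overlapping organs dominate, distant organs are nearly ignored.
ABUT_DISTANCE_MM = 5.0
NEAR_IMPORTANCE = 25.0
ABUT_IMPORTANCE = 60.0
FAR_IMPORTANCE = 4.0
EQUAL_IMPORTANCE = 40.0

OAR_THRESHOLD_GY = 35.0
R_OAR_PARAMS = {"cord": OarCostParams(20.0, 2.0, 30.0),
                "kidneys": OarCostParams(10.0, 2.0, 10.0)}


def default_target_params(prescription: float = 50.0,
                          offset: float = 0.0) -> TargetCostParams:
    return TargetCostParams(importance_lower=60.0, importance_upper=8.0,
                            power_lower=2.0, power_upper=2.0,
                            prescribed_dose=prescription, offset=offset)


def make_objective_specs(structures: StructureSet, prescription: float = 50.0,
                         grouping_distance: float = 30.0,
                         equal_weights: bool = False,
                         grouped_name: str = "grouped_oar"
                         ) -> tuple[ObjectiveSpec, ObjectiveSpec]:
    """Build matched (conventional, grouped) objective parameter sets.

    Conventional importances are distance-informed from the supplied
    (simulation-day) anatomy: organs abutting the PTV (min distance <=
    5 mm) get the highest importance, organs inside the grouping distance a
    medium one, and distant organs a token weight. With ``equal_weights``
    every primary OAR gets the same importance — the regime in which the
    grouped objective is an exact algebraic rewrite of the conventional one
    whenever all primary-OAR voxels lie within the grouping ring.
    """
    target = structures.target
    dist = distance_to_structure(target)
    tparams = default_target_params(prescription)

    conv_bindings = []
    for oar in structures.primary_oars:
        if equal_weights:
            w = EQUAL_IMPORTANCE
        else:
            dmin = float(dist[oar.voxels].min())
            if dmin <= ABUT_DISTANCE_MM:
                w = ABUT_IMPORTANCE
            elif dmin <= grouping_distance:
                w = NEAR_IMPORTANCE
            else:
                w = FAR_IMPORTANCE
        conv_bindings.append((oar.name, OarCostParams(w, 2.0, OAR_THRESHOLD_GY)))

    r_bindings = [(s.name, R_OAR_PARAMS.get(s.name, OarCostParams(10.0, 2.0, 30.0)))
                  for s in structures.r_oars]

    grouped_w = EQUAL_IMPORTANCE if equal_weights else ABUT_IMPORTANCE
    conv = ObjectiveSpec("conventional", (target.name, tparams),
                         conv_bindings, list(r_bindings))
    grouped = ObjectiveSpec("grouped", (target.name, tparams),
                            [(grouped_name,
                              OarCostParams(grouped_w, 2.0, OAR_THRESHOLD_GY))],
                            list(r_bindings))
    return conv, grouped


# ---------------------------------------------------------------------------
# Study scenarios
# ---------------------------------------------------------------------------

def _mismatch_templates(adjacent: bool) -> dict[str, OrganTemplate]:
    """Default organs with the large bowel either distant or adjacent."""
    organs = default_organ_templates()
    if adjacent:
        lb = Tube(((-35.0, 5.0, -20.0), (-34.0, 13.0, 0.0),
                   (-33.0, 20.0, 20.0)), 12.0)
    else:
        lb = Tube(((-85.0, 25.0, -30.0), (-82.0, 35.0, 0.0),
                   (-78.0, 45.0, 25.0)), 12.0)
    organs["large_bowel"] = OrganTemplate("large_bowel", Role.PRIMARY_OAR, (lb,))
    return organs


def scenario_mismatch(seed: int, grid: Grid | None = None,
                      prescription: float = 50.0
                      ) -> tuple[StructureSet, StructureSet,
                                 ObjectiveSpec, ObjectiveSpec]:
    """The mismatched-weighting scenario: a down-weighted organ moves in.

    At simulation the large bowel lies beyond the 30 mm grouping ring, so
    the distance-informed conventional weighting gives it a token
    importance. At the returned treatment fraction the large bowel sits
    adjacent to the PTV (minimum distance <= 5 mm). The conventional spec
    still carries the simulation-day weights (frozen, as in the adaptive
    workflow); the grouped spec carries a single primary-OAR parameter
    block. Both specs share the target block.
    """
    grid = grid or Grid((64, 64, 64), (4.0, 4.0, 4.0))
    sim_spec = PhantomSpec(grid=grid, organs=_mismatch_templates(False),
                           seed=seed)
    sim = generate_phantom(sim_spec, label=f"mismatch-sim(seed={seed})")

    frac_spec = dataclasses.replace(sim_spec, organs=_mismatch_templates(True))
    fraction_base = generate_phantom(frac_spec,
                                     label=f"mismatch-frac(seed={seed})")
    # Jitter the other organs between sessions; the relocated large bowel
    # stays exactly where the scenario puts it.
    deform = DeformationSpec(
        translation_mm=4.0, volume_change=0.08, seed=seed,
        per_organ={"large_bowel": OrganDeformation(0.0, 0.0)})
    fraction = simulate_fraction(fraction_base, deform, fraction_seed=seed)

    conv, grouped = make_objective_specs(sim, prescription=prescription)
    return sim, fraction, conv, grouped


def _compact_ring_templates() -> dict[str, OrganTemplate]:
    """Four small primary OARs placed disjointly, entirely within the ring."""
    organs = default_organ_templates()
    r_ptv = (3.0 * DEFAULT_PTV_VOLUME_CM3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    directions = {"stomach": (-1.0, -1.0, 0.3), "duodenum": (1.0, -0.8, -0.3),
                  "small_bowel": (-0.8, 1.0, -0.4), "large_bowel": (1.0, 1.0, 0.4)}
    for name, d in directions.items():
        d = np.asarray(d) / np.linalg.norm(d)
        center = tuple(d * (r_ptv + 2.0 + 11.0))
        organs[name] = OrganTemplate(name, Role.PRIMARY_OAR,
                                     (Ellipsoid(center, (11.0, 10.0, 10.0)),))
    return organs


def scenario_equal_weights(seed: int, grid: Grid | None = None,
                           prescription: float = 50.0
                           ) -> tuple[StructureSet, StructureSet,
                                      ObjectiveSpec, ObjectiveSpec]:
    """The comparable regime: equal weights, every OAR voxel inside the ring.

    Four compact disjoint primary OARs hug the PTV so that the grouped
    structure is exactly their union; with equal conventional weights the
    grouped objective is then an exact rewrite of the conventional one and
    the two planning modes should produce (near-)identical coverage.
    """
    grid = grid or Grid((64, 64, 64), (4.0, 4.0, 4.0))
    spec = PhantomSpec(grid=grid, organs=_compact_ring_templates(), seed=seed,
                       jitter_mm=2.0, radius_jitter=0.05)
    sim = generate_phantom(spec, label=f"equal-sim(seed={seed})")
    deform = DeformationSpec(translation_mm=3.0, volume_change=0.05, seed=seed)
    fraction = simulate_fraction(sim, deform, fraction_seed=seed)
    conv, grouped = make_objective_specs(sim, prescription=prescription,
                                         equal_weights=True)
    return sim, fraction, conv, grouped
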