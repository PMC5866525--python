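"""Toy beamlet dose engine: a dose field linear in beamlet weights.

The clinical system this sandbox emulates computes dose with a commercial
engine whose internals are not public; for a property-testable sandbox all
the planning method needs is a linear map from nonnegative beamlet weights
to a 3-D dose field with realistic-looking depth attenuation and lateral
penumbra. Each beam is a parallel (non-divergent) bundle of pencil beamlets
arranged on a square fluence grid perpendicular to the beam axis; a beamlet
deposits

    d(depth, r) = exp(-mu * depth) * exp(-r^2 / (2 * sigma^2)),   r <= 3 sigma

where ``depth`` is the distance (mm) from the grid entry plane along the
beam axis, ``r`` the lateral distance (mm) from the beamlet central axis,
``mu`` a linear attenuation coefficient and ``sigma`` the lateral Gaussian
penumbra width. Dose is in Gy per unit beamlet weight. The kernel is
truncated at 3 sigma. An optional density field scales geometric depth into
radiological depth. Beams rotate in the axial (x, y) plane about the grid
center, as a gantry does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .geometry import Grid


class BeamGeometryError(ValueError):
    """Raised when a beam deposits no dose anywhere in the grid."""


@dataclass(frozen=True)
class BeamConfig:
    """Beam and beamlet geometry shared by every plan in a comparison.

    ``gantry_angles`` are degrees in the axial plane; ``beamlets_per_beam``
    is the edge length of the square beamlet array (total beamlets per beam
    is its square, minus any that miss the grid); ``beamlet_width`` is the
    fluence-grid pitch in mm. Defaults (mu = 0.005 /mm, sigma = 4 mm,
    5 mm beamlets) give dose gradients of a realistic scale on 2-4 mm voxel
    grids.
    """

    gantry_angles: tuple[float, ...] = (0.0, 51.4, 102.9, 154.3, 205.7, 257.1, 308.6)
    beamlets_per_beam: int = 20
    beamlet_width: float = 5.0
    attenuation_coefficient: float = 0.005
    lateral_sigma: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gantry_angles",
                           tuple(float(a) for a in self.gantry_angles))
        if len(self.gantry_angles) < 1:
            raise ValueError("need at least one beam")
        if self.beamlets_per_beam < 1:
            raise ValueError("beamlets_per_beam must be >= 1")
        if self.beamlet_width <= 0:
            raise ValueError("beamlet_width must be > 0")
        if self.attenuation_coefficient < 0:
            raise ValueError("attenuation_coefficient must be >= 0")
        if self.lateral_sigma <= 0:
            raise ValueError("lateral_sigma must be > 0")


@dataclass
class InfluenceMatrix:
    """Beamlet-to-voxel dose mapping (Gy per unit weight).

    ``entries`` is a CSR sparse matrix of shape (n_beamlets, n_voxels) with
    voxels in C (row-major) order of the grid. ``beamlet_table`` records, per
    retained beamlet, (beam index, lateral offset u, longitudinal offset z)
    in mm relative to the grid center.
    """

    entries: sparse.csr_matrix
    grid: Grid
    beam_config: BeamConfig
    beamlet_table: np.ndarray  # (n_beamlets, 3): beam index, u, z

    @property
    def n_beamlets(self) -> int:
        return self.entries.shape[0]


def _beam_axes(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit beam direction and in-plane lateral axis for a gantry angle."""
    a = np.deg2rad(angle_deg)
    direction = np.array([np.cos(a), np.sin(a), 0.0])
    lateral = np.array([-np.sin(a), np.cos(a), 0.0])
    return direction, lateral


def _radiological_depth(depth: np.ndarray, coords: np.ndarray,
                        direction: np.ndarray, grid: Grid,
                        density: np.ndarray, n_steps: int = 24) -> np.ndarray:
    """Approximate line integral of density from the entry plane to each voxel.

    Midpoint rule with ``n_steps`` samples per ray; adequate for the smooth
    density fields this sandbox uses (dose accuracy is not the contribution).
    """
    from scipy.ndimage import map_coordinates

    steps = (np.arange(n_steps) + 0.5) / n_steps
    rad = np.zeros_like(depth)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    for s in steps:
        pts = coords - np.outer(depth * (1.0 - s), direction)
        idx = ((pts - origin) / spacing - 0.5).T
        rad += map_coordinates(density, idx, order=1, mode="nearest")
    return rad * depth / n_steps


def build_influence(grid: Grid, beams: BeamConfig,
                    density: np.ndarray | None = None) -> InfluenceMatrix:
    """Assemble the sparse influence matrix for a grid and beam configuration.

    Deterministic given its inputs. Beamlets whose 3-sigma footprint misses
    the grid entirely are dropped; a beam losing all of its beamlets raises
    :class:`BeamGeometryError`.
    """
    if density is not None:
        density = np.asarray(density, dtype=float)
        if density.shape != grid.shape:
            raise ValueError("density field shape must match grid shape")

    coords = grid.voxel_centers()
    center = np.asarray(grid.origin) + 0.5 * np.asarray(grid.extent_mm())
    zc = coords[:, 2] - center[2]
    sigma = beams.lateral_sigma
    cut = 3.0 * sigma
    mu = beams.attenuation_coefficient
    n = beams.beamlets_per_beam
    offsets = (np.arange(n) - (n - 1) / 2.0) * beams.beamlet_width

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    table: list[tuple[int, float, float]] = []
    beamlet_idx = 0

    for bi, angle in enumerate(beams.gantry_angles):
        direction, lateral = _beam_axes(angle)
        proj = coords @ direction
        depth = proj - proj.min()
        if density is None:
            axial = np.exp(-mu * depth)
        else:
            axial = np.exp(-mu * _radiological_depth(
                depth, coords, direction, grid, density))
        uc = (coords - center) @ lateral

        order = np.argsort(uc, kind="stable")
        uc_sorted = uc[order]
        kept_any = False
        for u_off in offsets:
            lo = np.searchsorted(uc_sorted, u_off - cut, side="left")
            hi = np.searchsorted(uc_sorted, u_off + cut, side="right")
            cand = order[lo:hi]
            if cand.size == 0:
                continue
            du = uc[cand] - u_off
            for z_off in offsets:
                dz = zc[cand] - z_off
                r2 = du * du + dz * dz
                inside = r2 <= cut * cut
                if not inside.any():
                    continue
                vox = cand[inside]
                kept_any = True
                vals.append(axial[vox] * np.exp(-r2[inside] / (2.0 * sigma * sigma)))
                cols.append(vox)
                rows.append(np.full(vox.size, beamlet_idx, dtype=np.int64))
                table.append((bi, float(u_off), float(z_off)))
                beamlet_idx += 1
        if not kept_any:
            raise BeamGeometryError(
                f"beam {bi} (gantry {angle} deg) misses the grid entirely")

    entries = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(beamlet_idx, grid.n_voxels))
    return InfluenceMatrix(entries, grid, beams, np.asarray(table, dtype=float))


def compute_dose(influence: InfluenceMatrix, weights: np.ndarray) -> np.ndarray:
    """Dose field (Gy, grid shape) for nonnegative beamlet weights."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (influence.n_beamlets,):
        raise ValueError(
            f"expected {influence.n_beamlets} weights, got shape {weights.shape}")
    if np.any(weights < 0):
        raise ValueError("beamlet weights must be nonnegative")
    flat = influence.entries.T @ weights
    return flat.reshape(influence.grid.shape)
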