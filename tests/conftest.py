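import numpy as np
import pytest

from oargroup import (BeamConfig, Grid, Role, StructureMask, StructureSet,
                      build_influence)


def make_random_mask(grid: Grid, rng: np.random.Generator, p: float = 0.1,
                     name: str = "m", role: Role = Role.PRIMARY_OAR
                     ) -> StructureMask:
    vox = rng.random(grid.shape) < p
    if not vox.any():
        vox.flat[rng.integers(0, vox.size)] = True
    return StructureMask(grid, vox, name, role)


def brute_force_distance(mask: StructureMask) -> np.ndarray:
    """O(N * n_true) oracle: min center-to-center distance to the mask."""
    centers = mask.grid.voxel_centers()
    true_centers = centers[mask.voxels.ravel()]
    d = np.full(centers.shape[0], np.inf)
    for t in true_centers:
        d = np.minimum(d, np.sqrt(np.sum((centers - t) ** 2, axis=1)))
    return d.reshape(mask.grid.shape)


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    return Grid((12, 12, 12), (4.0, 5.0, 3.0))


@pytest.fixture(scope="session")
def tiny_influence():
    """A 10^3 isotropic grid with 2 beams x 3x3 beamlets for solver tests."""
    grid = Grid((10, 10, 10), (8.0, 8.0, 8.0))
    beams = BeamConfig(gantry_angles=(0.0, 90.0), beamlets_per_beam=3,
                       beamlet_width=12.0, lateral_sigma=8.0)
    return build_influence(grid, beams)


def simple_structures(grid: Grid, rng: np.random.Generator,
                      n_oars: int = 2) -> StructureSet:
    """A central blob target plus a few random OARs for solver tests."""
    centers = grid.voxel_centers()
    mid = np.asarray(grid.origin) + 0.5 * np.asarray(grid.extent_mm())
    r = 0.22 * min(grid.extent_mm())
    target = (np.sum((centers - mid) ** 2, axis=1) <= r * r).reshape(grid.shape)
    masks = [StructureMask(grid, target, "ptv", Role.TARGET)]
    for i in range(n_oars):
        off = rng.uniform(-0.3, 0.3, 3) * np.asarray(grid.extent_mm())
        ro = rng.uniform(0.1, 0.2) * min(grid.extent_mm())
        vox = (np.sum((centers - mid - off) ** 2, axis=1) <= ro * ro
               ).reshape(grid.shape) & ~target
        if not vox.any():
            vox.flat[0] = True
        masks.append(StructureMask(grid, vox, f"oar{i}", Role.PRIMARY_OAR))
    return StructureSet(grid, masks, "toy")
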