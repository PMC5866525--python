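"""Voxel-grid structure representation and mask geometry.

Everything downstream — the beamlet dose engine, the objective, DVH metrics —
operates on boolean structure masks defined on one shared regular grid. This
module provides the grid/mask containers plus the handful of geometric
operations the grouping method needs: anisotropic Euclidean distance
transforms, margin expansion, the distance-bounded union that builds the
grouped organ-at-risk (OAR) structure, and the optimized planning target
volume (PTV-OPT, the PTV minus margin-expanded OARs).

Conventions: voxel indices are 0-based; distances and margins are in mm;
volumes are reported in cm^3; grids may be anisotropic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage


class EmptyStructureError(ValueError):
    """Raised when an operation requires a structure with at least one voxel."""


class Role(str, enum.Enum):
    """Planning role of a structure.

    ``TARGET`` is the planning target volume (PTV); ``PRIMARY_OAR`` marks the
    deformable gastrointestinal organs that share a single volumetric dose
    constraint (stomach, duodenum, small bowel, large bowel) and participate
    in grouping; ``R_OAR`` marks remaining OARs (spinal cord, kidneys) that
    keep individual penalty terms in both planning modes.
    """

    TARGET = "target"
    PRIMARY_OAR = "primary_oar"
    R_OAR = "r_oar"


@dataclass(frozen=True)
class Grid:
    """Regular voxel grid: ``shape`` voxels per axis, ``spacing`` mm per axis.

    ``origin`` is the physical (mm) position of the corner of voxel
    (0, 0, 0); voxel centers sit at ``origin + (index + 0.5) * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Grid shape, spacing and origin must be length-3")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def voxel_centers(self) -> np.ndarray:
        """Physical centers of all voxels, shape (n_voxels, 3), C order, mm."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(self.shape[a] * self.spacing[a] for a in range(3))


@dataclass
class StructureMask:
    """A named boolean structure on a grid, tagged with its planning role."""

    grid: Grid
    voxels: np.ndarray
    name: str
    role: Role

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        self.role = Role(self.role)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask {self.name!r}: voxel field shape {self.voxels.shape} "
                f"does not match grid shape {self.grid.shape}"
            )

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    def with_voxels(self, voxels: np.ndarray, name: str | None = None,
                    role: Role | None = None) -> "StructureMask":
        return StructureMask(self.grid, voxels, name or self.name,
                             role or self.role)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StructureMask):
            return NotImplemented
        return (self.grid == other.grid and self.name == other.name
                and self.role == other.role
                and np.array_equal(self.voxels, other.voxels))


@dataclass
class StructureSet:
    """Ordered collection of masks on one grid — the anatomy of one session.

    Exactly one mask carries the target role; names are unique. ``label``
    records provenance (which phantom/fraction produced this anatomy).
    """

    grid: Grid
    structures: list[StructureMask] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise ValueError(f"structure names must be unique, got {names}")
        for s in self.structures:
            if s.grid != self.grid:
                raise ValueError(f"structure {s.name!r} is on a different grid")
        n_targets = sum(s.role is Role.TARGET for s in self.structures)
        if n_targets != 1:
            raise ValueError(f"a StructureSet needs exactly one target, got {n_targets}")

    @property
    def target(self) -> StructureMask:
        return next(s for s in self.structures if s.role is Role.TARGET)

    @property
    def primary_oars(self) -> list[StructureMask]:
        return [s for s in self.structures if s.role is Role.PRIMARY_OAR]

    @property
    def r_oars(self) -> list[StructureMask]:
        return [s for s in self.structures if s.role is Role.R_OAR]

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.structures]

    def __getitem__(self, name: str) -> StructureMask:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named {name!r} "
                       f"(available: {self.names})")

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.structures)

    def __iter__(self) -> Iterator[StructureMask]:
        return iter(self.structures)

    def with_structure(self, mask: StructureMask, replace_existing: bool = False
                       ) -> "StructureSet":
        """Return a new set with ``mask`` appended (or replacing a namesake)."""
        structures = list(self.structures)
        if mask.name in self:
            if not replace_existing:
                raise ValueError(f"structure {mask.name!r} already present")
            structures = [mask if s.name == mask.name else s for s in structures]
        else:
            structures.append(mask)
        return StructureSet(self.grid, structures, self.label)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def distance_to_structure(mask: StructureMask) -> np.ndarray:
    """Euclidean distance (mm) from every voxel center to the structure.

    Distances are measured between voxel centers using the grid's anisotropic
    spacing; voxels inside the mask have distance 0.
    """
    if mask.is_empty:
        raise EmptyStructureError(
            f"structure {mask.name!r} has no voxels; distance is undefined")
    return ndimage.distance_transform_edt(
        ~mask.voxels, sampling=mask.grid.spacing)


def expand_mask(mask: StructureMask, margin: float) -> StructureMask:
    """Expand a mask by a Euclidean margin (mm), boundary-inclusive.

    A voxel is included iff its center lies within ``margin`` of the nearest
    mask voxel center. ``margin = 0`` returns the mask unchanged.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    if margin == 0:
        return mask.with_voxels(mask.voxels.copy())
    dist = distance_to_structure(mask)
    return mask.with_voxels(dist <= margin)


def group_oars(structures: StructureSet, distance_limit: float = 30.0,
               name: str = "grouped_oar") -> StructureMask:
    """Build the grouped OAR: primary-OAR voxels within ``distance_limit`` of
    the target, unioned into a single structure.

    The limit is a 3-D center-to-center Euclidean distance and is
    boundary-inclusive (a voxel exactly at the limit is kept). Voxels where
    primary OARs overlap are counted once. Default limit 30 mm (3 cm).
    """
    primaries = structures.primary_oars
    if not primaries:
        raise EmptyStructureError("StructureSet has no primary OARs to group")
    dist = distance_to_structure(structures.target)
    ring = dist <= distance_limit
    union = np.zeros(structures.grid.shape, dtype=bool)
    for oar in primaries:
        union |= oar.voxels
    return StructureMask(structures.grid, union & ring, name, Role.PRIMARY_OAR)


def make_ptv_opt(target: StructureMask, primary_oars: Sequence[StructureMask],
                 margin: float = 5.0, name: str = "ptv_opt") -> StructureMask:
    """PTV-OPT: the target minus every primary OAR expanded by ``margin`` mm.

    This is the portion of the target where full dose is achievable without
    violating OAR limits. The result may be empty (check ``is_empty``) — an
    empty PTV-OPT is a legitimate anatomical situation, not an error.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    carved = target.voxels.copy()
    for oar in primary_oars:
        if oar.grid != target.grid:
            raise ValueError(f"OAR {oar.name!r} is on a different grid")
        if oar.is_empty:
            continue
        carved &= ~expand_mask(oar, margin).voxels
    return StructureMask(target.grid, carved, name, Role.TARGET)


def mask_volume(mask: StructureMask) -> float:
    """Structure volume in cm^3 (true-voxel count times voxel volume)."""
    return mask.voxel_count * mask.grid.voxel_volume_cm3
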