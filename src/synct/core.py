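"""Shared data model: grids, CT volumes, structure masks and dose grids.

Every array in the package travels with its geometry.  The canonical
axis order is ``(x, y, z)`` with ``z`` the axial (slice) axis; voxel
indices are 0-based and a voxel's world position is its **center**:
``world = origin + index * spacing`` (mm).  ROI boxes are half-open
``[start, start + size)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HU_MIN, HU_MAX = -1024.0, 3071.0


class GeometryError(ValueError):
    """Grids that should match do not, or a grid is malformed."""


@dataclass(frozen=True)
class Grid:
    """Regular 3-D voxel lattice: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3:
            raise GeometryError("grids are three-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    def voxel_centers(self):
        """World-coordinate (mm) center of every voxel, as three 1-D axes."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def same_as(self, other, atol=1e-6):
        return (self.shape == other.shape
                and np.allclose(self.spacing, other.spacing, atol=atol)
                and np.allclose(self.origin, other.origin, atol=atol))

    @property
    def extent(self):
        """Physical size along each axis in mm (shape x spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def voxel_volume_cc(self):
        return float(np.prod(self.spacing)) / 1000.0


def _check_grid_match(a, b, what="operands"):
    if not a.same_as(b):
        raise GeometryError(f"{what} are on different grids: {a} vs {b}")


@dataclass
class CTVolume:
    """3-D scalar field in Hounsfield units on a :class:`Grid`."""

    voxels: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.shape != self.grid.shape:
            raise GeometryError(
                f"voxel shape {self.voxels.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CT volume contains non-finite values")

    @property
    def spacing(self):
        return self.grid.spacing

    @property
    def origin(self):
        return self.grid.origin

    def copy(self):
        return CTVolume(self.voxels.copy(), self.grid)


@dataclass
class PairedSample:
    """Co-registered NCT/CECT pair sharing one grid."""

    nct: CTVolume
    cect: CTVolume

    def __post_init__(self):
        _check_grid_match(self.nct.grid, self.cect.grid, "NCT and CECT")

    @property
    def grid(self):
        return self.nct.grid


@dataclass
class StructureMask:
    """Named binary volume on a reference grid."""

    name: str
    mask: np.ndarray
    grid: Grid
    empty_ok: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}")

    @property
    def is_empty(self):
        return not self.mask.any()

    @property
    def volume_cc(self):
        return float(self.mask.sum()) * self.grid.voxel_volume_cc

    def voxel_count(self):
        return int(self.mask.sum())


@dataclass
class DoseGrid:
    """3-D absorbed-dose field in Gy."""

    voxels: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.shape != self.grid.shape:
            raise GeometryError(
                f"dose shape {self.voxels.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("dose grid contains non-finite values")
        if self.voxels.min() < 0:
            raise ValueError("dose must be non-negative")


# The seven delineation targets: whole heart, four chambers, two vessels.
CANONICAL_STRUCTURES = ("heart", "lv", "la", "rv", "ra", "lad", "rca")
VESSEL_STRUCTURES = ("lad", "rca")
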