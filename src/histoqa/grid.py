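"""Voxel-grid containers used throughout the pipeline.

World coordinates are millimetres. A grid is defined by an isotropic voxel
spacing and a world origin; the world position of voxel ``(i, j, k)`` is
``origin + spacing * (i, j, k)`` evaluated at the voxel centre. Array axes
map to world axes as ``values[ix, iy, iz]`` with Z the direction of
ultrasound propagation (layers are normal to Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "BinaryMask", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Two objects expected to share a voxel grid do not."""


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass
class Volume:
    """A 3D scalar image on an isotropic voxel grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar attenuation values (arbitrary units).
    spacing_mm : float
        Isotropic voxel spacing in mm; must be positive.
    origin_mm : array-like of 3 floats
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        self.origin_mm = _as_vec3(self.origin_mm)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def world_axes(self) -> tuple:
        """Per-axis world coordinate vectors of voxel centres."""
        return tuple(
            self.origin_mm[a] + self.spacing_mm * np.arange(self.shape[a])
            for a in range(3)
        )

    def index_from_world(self, pts_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices for world points (N, 3)."""
        pts = np.atleast_2d(np.asarray(pts_mm, dtype=float))
        return (pts - self.origin_mm) / self.spacing_mm

    def world_from_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin_mm + self.spacing_mm * idx

    def same_grid(self, other: "Volume | BinaryMask", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing_mm - other.spacing_mm) <= tol
            and bool(np.all(np.abs(self.origin_mm - other.origin_mm) <= tol))
        )

    def require_same_grid(self, other: "Volume | BinaryMask") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: {self.shape}/{self.spacing_mm}/{self.origin_mm} vs "
                f"{other.shape}/{other.spacing_mm}/{other.origin_mm}"
            )

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing_mm, self.origin_mm.copy())


@dataclass
class BinaryMask:
    """A boolean voxel mask aligned to a :class:`Volume` grid."""

    values: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if not self.spacing_mm > 0:
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        self.origin_mm = _as_vec3(self.origin_mm)

    # grid protocol shared with Volume
    shape = Volume.shape
    world_axes = Volume.world_axes
    index_from_world = Volume.index_from_world
    world_from_index = Volume.world_from_index
    same_grid = Volume.same_grid
    require_same_grid = Volume.require_same_grid

    @property
    def n_true(self) -> int:
        return int(self.values.sum())

    def world_coords_of_true(self) -> np.ndarray:
        """World coordinates (N, 3) of the centres of all True voxels."""
        idx = np.argwhere(self.values)
        return self.origin_mm + self.spacing_mm * idx

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.values.copy(), self.spacing_mm, self.origin_mm.copy())
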