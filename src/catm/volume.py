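"""Voxel volumes with physical metadata.

A :class:`Volume` carries a 3D scalar grid together with its isotropic voxel
size (nm/voxel) and the physical position of the center of voxel
``(0, 0, 0)``.  Arrays are indexed ``data[iz, iy, ix]`` (numpy/MRC section
order) while physical coordinates are ``(x, y, z)`` in nanometers; the two
conventions meet only in this module, so everything downstream can speak nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3D scalar grid with voxel size and origin.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar field, indexed ``[iz, iy, ix]``.
    voxel_size : float
        Isotropic voxel edge length in nm; must be positive.
    origin : ndarray, shape (3,)
        Physical (x, y, z) position in nm of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: float = 1.0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("grid dimensions must be >= 1 along each axis")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data values must be finite")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (nz, ny, nx)

    @property
    def shape_xyz(self) -> np.ndarray:
        """Grid extents as (nx, ny, nz)."""
        nz, ny, nx = self.data.shape
        return np.array([nx, ny, nz])

    @property
    def center_nm(self) -> np.ndarray:
        """Physical (x, y, z) of the grid center (may fall between voxels)."""
        return self.origin + (self.shape_xyz - 1) / 2.0 * self.voxel_size

    def nm_to_voxel(self, pos_nm: np.ndarray) -> np.ndarray:
        """Convert physical (x, y, z) nm to fractional voxel indices (x, y, z)."""
        return (np.asarray(pos_nm, dtype=float) - self.origin) / self.voxel_size

    def voxel_to_nm(self, idx_xyz: np.ndarray) -> np.ndarray:
        """Convert (possibly fractional) voxel indices (x, y, z) to nm."""
        return np.asarray(idx_xyz, dtype=float) * self.voxel_size + self.origin

    def contains_nm(self, pos_nm: np.ndarray, margin_nm: float = 0.0) -> bool:
        """True if the physical point lies inside the grid, with optional margin."""
        v = self.nm_to_voxel(pos_nm)
        m = margin_nm / self.voxel_size
        return bool(np.all(v >= m) and np.all(v <= self.shape_xyz - 1 - m))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size, self.origin.copy())

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume sharing this grid's metadata."""
        return Volume(np.asarray(data), self.voxel_size, self.origin.copy())
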