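"""Voxelized occupancy bookkeeping for steric-clash tests.

Placed particles are represented by their rotated steric masks rasterized
into a shared integer grid.  Overlap between a candidate pose and the
current occupancy is a voxel count, so clash criteria can be expressed as
"more than `tol` voxels shared" or as a fraction of the mask volume.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .templates import rotate_mask
from .volume import Volume

__all__ = ["mask_voxel_indices", "OccupancyGrid"]


def mask_voxel_indices(mask: Volume, rotation: Rotation, position_nm: np.ndarray,
                       frame: Volume) -> np.ndarray:
    """Flat voxel indices covered by a rotated mask placed at a position.

    The mask is rotated with nearest-neighbor resampling and its center
    snapped to the nearest voxel of ``frame`` (sub-voxel shifts are below
    the fidelity of a binary mask).  Out-of-frame voxels are dropped.
    """
    rot = rotate_mask(mask, rotation)
    offs = np.argwhere(rot.data > 0.5)  # (k, 3) in (z, y, x)
    c = (np.array(rot.data.shape) - 1) // 2
    center_xyz = np.rint(frame.nm_to_voxel(position_nm)).astype(int)
    center_zyx = center_xyz[::-1]
    vox = offs - c + center_zyx
    shape = np.array(frame.data.shape)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[ok]
    return np.ravel_multi_index(vox.T, frame.data.shape)


class OccupancyGrid:
    """Additive occupancy counts over a volume frame.

    Supports insertion/removal of particles (identified by integer keys)
    and overlap queries for candidate voxel sets.
    """

    def __init__(self, frame: Volume):
        self.frame = frame
        self.counts = np.zeros(frame.data.size, dtype=np.int16)
        self._placed: dict[int, np.ndarray] = {}

    def overlap(self, flat_indices: np.ndarray) -> int:
        """Number of candidate voxels already occupied."""
        if len(flat_indices) == 0:
            return 0
        return int(np.count_nonzero(self.counts[flat_indices]))

    def insert(self, key: int, flat_indices: np.ndarray) -> None:
        if key in self._placed:
            raise KeyError(f"particle {key} already placed")
        self.counts[flat_indices] += 1
        self._placed[key] = flat_indices

    def remove(self, key: int) -> np.ndarray:
        idx = self._placed.pop(key)
        self.counts[idx] -= 1
        return idx

    def __contains__(self, key: int) -> bool:
        return key in self._placed

    @property
    def occupancy_volume(self) -> Volume:
        """Binary occupancy map as a Volume."""
        data = (self.counts > 0).astype(np.float32).reshape(self.frame.data.shape)
        return self.frame.with_data(data)
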