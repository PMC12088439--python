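"""Rigid-body orientations and orientation grids.

Orientations are proper rotations stored as scipy ``Rotation`` objects
(unit quaternions internally).  At I/O boundaries they become intrinsic
ZYZ Euler angles in degrees, written as the loose Relion triplet
``(rot, tilt, psi)``.  A particle's "normal" is the image of the local +z
axis (the disc axis of a nucleosome template) under its rotation.

The disc template used throughout this package is cylindrically symmetric
about its local z axis and symmetric under flipping top for bottom, so an
orientation is physically identified with the axis it sends +z to, up to
sign.  Orientation grids and angular errors both respect that symmetry.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "euler_to_rotation",
    "rotation_to_euler",
    "rotation_from_axis",
    "normal_axis",
    "angle_between_axes",
    "random_rotations",
    "RotationGrid",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def euler_to_rotation(rot: float, tilt: float, psi: float) -> Rotation:
    """Intrinsic ZYZ Euler angles (degrees) -> Rotation."""
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True)


def rotation_to_euler(r: Rotation) -> np.ndarray:
    """Rotation -> intrinsic ZYZ Euler angles (rot, tilt, psi) in degrees."""
    return r.as_euler("ZYZ", degrees=True)


def rotation_from_axis(axis: np.ndarray) -> Rotation:
    """Rotation taking +z to ``axis`` with zero in-plane angle.

    ``axis`` need not be normalized.  The result has ZYZ Euler angles
    (phi, theta, 0) where (theta, phi) are the polar coordinates of the axis.
    """
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    theta = np.degrees(np.arccos(np.clip(a[2], -1.0, 1.0)))
    phi = np.degrees(np.arctan2(a[1], a[0]))
    return Rotation.from_euler("ZYZ", [phi, theta, 0.0], degrees=True)


def normal_axis(r: Rotation) -> np.ndarray:
    """Image of the local +z axis (disc normal), shape (3,) or (n, 3)."""
    return r.apply([0.0, 0.0, 1.0])


def angle_between_axes(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two axes with antipodal identification, in [0, 90]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dot = np.abs(np.sum(a * b, axis=-1)) / (
        np.linalg.norm(a, axis=-1) * np.linalg.norm(b, axis=-1)
    )
    return np.degrees(np.arccos(np.clip(dot, -1.0, 1.0)))


def random_rotations(n: int, rng: np.random.Generator) -> Rotation:
    """Draw n rotations uniformly from SO(3)."""
    return Rotation.random(n, random_state=rng)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n quasi-uniform directions on the upper hemisphere (z >= 0)."""
    i = np.arange(n)
    z = (i + 0.5) / n  # cos(theta) in (0, 1): upper hemisphere
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


class RotationGrid:
    """Quasi-uniform orientation grid with a stated angular step.

    For a disc-symmetric template (continuous in-plane symmetry plus
    top-bottom flip) the grid samples only the axis direction, over the
    upper hemisphere (antipodal identification).  For asymmetric templates
    an in-plane angle loop is added, giving a full SO(3) product grid.

    Parameters
    ----------
    angular_step : float
        Target covering resolution in degrees.
    symmetry : {"disc", "c1"}
        "disc": axis-only grid (default).  "c1": full SO(3).
    """

    def __init__(self, angular_step: float = 15.0, symmetry: str = "disc"):
        if angular_step <= 0:
            raise ValueError("angular_step must be positive")
        if symmetry not in ("disc", "c1"):
            raise ValueError(f"unknown symmetry {symmetry!r}")
        self.angular_step = float(angular_step)
        self.symmetry = symmetry
        step = np.radians(angular_step)
        # hemisphere area 2*pi; one point per step^2 keeps the covering
        # radius (~0.62*sqrt(area per point)) below the stated step
        n_axes = max(4, int(np.ceil(2.0 * np.pi / step**2)))
        axes = _fibonacci_hemisphere(n_axes)
        if symmetry == "disc":
            rots = [rotation_from_axis(a) for a in axes]
        else:
            n_psi = max(1, int(np.ceil(360.0 / angular_step)))
            psis = np.arange(n_psi) * (360.0 / n_psi)
            rots = []
            for a in axes:
                base = rotation_from_axis(a)
                for psi in psis:
                    rots.append(base * Rotation.from_euler("z", psi, degrees=True))
        self.orientations: Rotation = Rotation.concatenate(rots)

    def __len__(self) -> int:
        return len(self.orientations)

    def __iter__(self):
        return iter(self.orientations)
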