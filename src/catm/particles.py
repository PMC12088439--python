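"""Particle tables: positions, orientations, scores.

A :class:`ParticleSet` wraps a pandas DataFrame with the canonical columns

    x, y, z        position in nm
    rot, tilt, psi intrinsic ZYZ Euler angles in degrees
    score          matching score (CCC), NaN if not scored
    kind           particle species label (e.g. "nucleosome_disc")

plus any extra columns callers attach (class labels, cluster ids, ...).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .orientation import normal_axis

__all__ = ["ParticleSet", "COLUMNS"]

COLUMNS = ["x", "y", "z", "rot", "tilt", "psi", "score", "kind"]


class ParticleSet:
    """Table of particle records (positions nm, ZYZ Euler degrees)."""

    def __init__(self, table: pd.DataFrame | None = None):
        if table is None:
            table = pd.DataFrame(columns=COLUMNS)
        table = table.copy().reset_index(drop=True)
        for col, default in (("rot", 0.0), ("tilt", 0.0), ("psi", 0.0),
                             ("score", np.nan), ("kind", "nucleosome_disc")):
            if col not in table.columns:
                table[col] = default
        missing = [c for c in ("x", "y", "z") if c not in table.columns]
        if missing:
            raise ValueError(f"particle table missing columns {missing}")
        self.table = table

    @classmethod
    def from_arrays(cls, positions: np.ndarray,
                    rotations: Rotation | None = None,
                    scores: np.ndarray | None = None,
                    kinds=None) -> "ParticleSet":
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        df = pd.DataFrame(positions, columns=["x", "y", "z"])
        if rotations is not None and n:
            import warnings
            with warnings.catch_warnings():
                # gimbal lock at tilt 0/180 is harmless here: the in-plane
                # angle is degenerate for the symmetric disc anyway
                warnings.filterwarnings("ignore", message="Gimbal lock")
                eul = np.atleast_2d(rotations.as_euler("ZYZ", degrees=True))
            df[["rot", "tilt", "psi"]] = eul
        if scores is not None:
            df["score"] = np.asarray(scores, dtype=float)
        if kinds is not None:
            df["kind"] = kinds
        return cls(df)

    # -- accessors ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) positions in nm, columns (x, y, z)."""
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def rotations(self) -> Rotation:
        eul = self.table[["rot", "tilt", "psi"]].to_numpy(dtype=float)
        return Rotation.from_euler("ZYZ", eul, degrees=True)

    @property
    def normals(self) -> np.ndarray:
        """(n, 3) disc-normal axes (image of local +z)."""
        return np.atleast_2d(normal_axis(self.rotations))

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy(dtype=float)

    @property
    def kinds(self) -> np.ndarray:
        return self.table["kind"].to_numpy()

    def select(self, mask) -> "ParticleSet":
        return ParticleSet(self.table[np.asarray(mask)])

    def of_kind(self, kind: str) -> "ParticleSet":
        return self.select(self.table["kind"].to_numpy() == kind)

    def copy(self) -> "ParticleSet":
        return ParticleSet(self.table)

    @staticmethod
    def concat(parts: list["ParticleSet"]) -> "ParticleSet":
        frames = [p.table for p in parts if len(p)]
        if not frames:
            return ParticleSet()
        return ParticleSet(pd.concat(frames, ignore_index=True))

    def __repr__(self) -> str:
        return f"ParticleSet(n={len(self)})"
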