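"""Standard-format I/O: MRC volumes, STAR/CSV particle tables.

Internal units are nanometers everywhere; voxel units appear only at
format boundaries.  MRC headers record the voxel size in Angstrom (the
cryo-EM convention) as cell dimensions / grid size, and the origin in the
ORIGIN header words.  STAR tables use the loose Relion dialect: coordinates
in voxels (``rlnCoordinateX/Y/Z``), intrinsic ZYZ Euler angles in degrees
(``rlnAngleRot/Tilt/Psi``), plus a score column.  CSV tables carry
positions directly in nm.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd

from .particles import ParticleSet
from .volume import Volume

__all__ = ["read_volume", "write_volume", "read_particles", "write_particles"]

_NM_PER_ANGSTROM = 0.1


def write_volume(v: Volume, path: str) -> None:
    """Write a Volume as a mode-2 (float32) MRC/CCP4 map."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(v.data, dtype=np.float32))
    nz, ny, nx = v.data.shape
    vs_a = v.voxel_size / _NM_PER_ANGSTROM
    m.grid.unit_cell = gemmi.UnitCell(nx * vs_a, ny * vs_a, nz * vs_a,
                                      90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    ox, oy, oz = v.origin / _NM_PER_ANGSTROM
    m.set_header_float(50, ox)
    m.set_header_float(51, oy)
    m.set_header_float(52, oz)
    m.write_ccp4_map(path)


def read_volume(path: str, atol: float = 1e-4) -> Volume:
    """Read an MRC/CCP4 map into a Volume (requires isotropic voxels)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    m = gemmi.read_ccp4_map(path)
    data = np.array(m.grid, copy=True)
    nz, ny, nx = data.shape
    cell = m.grid.unit_cell
    vs = np.array([cell.a / nx, cell.b / ny, cell.c / nz]) * _NM_PER_ANGSTROM
    if np.ptp(vs) > atol * vs.mean():
        raise ValueError(
            f"isotropic voxel size required, got {vs} nm; resample first")
    origin = np.array([m.header_float(i) for i in (50, 51, 52)]) * _NM_PER_ANGSTROM
    return Volume(data, float(vs.mean()), origin)


_STAR_COLUMNS = {
    "rlnCoordinateX": "x", "rlnCoordinateY": "y", "rlnCoordinateZ": "z",
    "rlnAngleRot": "rot", "rlnAngleTilt": "tilt", "rlnAnglePsi": "psi",
    "rlnScore": "score",
}

_CSV_COLUMNS = {"x_nm": "x", "y_nm": "y", "z_nm": "z",
                "rot_deg": "rot", "tilt_deg": "tilt", "psi_deg": "psi",
                "score": "score", "kind": "kind"}


def write_particles(ps: ParticleSet, path: str, voxel_size: float = 1.0) -> None:
    """Write a particle table as STAR (voxel coordinates) or CSV (nm).

    Format is chosen by extension (.star or .csv).
    """
    if path.endswith(".star"):
        doc = gemmi.cif.Document()
        blk = doc.add_new_block("particles")
        tags = ["CoordinateX", "CoordinateY", "CoordinateZ",
                "AngleRot", "AngleTilt", "AnglePsi", "Score"]
        loop = blk.init_loop("_rln", tags)
        t = ps.table
        for _, row in t.iterrows():
            loop.add_row([
                f"{row.x / voxel_size:.6f}", f"{row.y / voxel_size:.6f}",
                f"{row.z / voxel_size:.6f}",
                f"{row.rot:.6f}", f"{row.tilt:.6f}", f"{row.psi:.6f}",
                "nan" if pd.isna(row.score) else f"{row.score:.6f}",
            ])
        doc.write_file(path)
    elif path.endswith(".csv"):
        out = pd.DataFrame({
            "x_nm": ps.table.x, "y_nm": ps.table.y, "z_nm": ps.table.z,
            "rot_deg": ps.table.rot, "tilt_deg": ps.table.tilt,
            "psi_deg": ps.table.psi, "score": ps.table.score,
            "kind": ps.table.kind,
        })
        out.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown particle format for {path!r} (.star or .csv)")


def read_particles(path: str, voxel_size: float = 1.0) -> ParticleSet:
    """Read a STAR or CSV particle table into a ParticleSet (positions nm)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if path.endswith(".star"):
        doc = gemmi.cif.read_file(path)
        blk = doc.sole_block()
        data = {}
        for tag, col in _STAR_COLUMNS.items():
            loop = blk.find_loop(f"_{tag}")
            vals = list(loop)
            if vals:
                data[col] = np.array(vals, dtype=float)
        for req in ("x", "y", "z"):
            if req not in data:
                raise ValueError(f"STAR file missing mandatory column "
                                 f"_rlnCoordinate{req.upper()}")
        df = pd.DataFrame(data)
        for c in ("x", "y", "z"):
            df[c] = df[c] * voxel_size
        return ParticleSet(df)
    if path.endswith(".csv"):
        raw = pd.read_csv(path)
        missing = [c for c in ("x_nm", "y_nm", "z_nm") if c not in raw.columns]
        if missing:
            raise ValueError(f"CSV missing mandatory columns {missing}")
        df = raw.rename(columns=_CSV_COLUMNS)
        keep = [c for c in df.columns
                if c in ("x", "y", "z", "rot", "tilt", "psi", "score", "kind")]
        return ParticleSet(df[keep])
    raise ValueError(f"unknown particle format for {path!r} (.star or .csv)")
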