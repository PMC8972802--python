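"""Standard-format readers and writers: MRC2014 volumes, STAR/CSV particle tables.

Volumes go through gemmi's CCP4/MRC map support (mode 2, 32-bit float,
voxel size in the header).  Particle metadata uses a RELION-style
``data_particles`` STAR loop (angles in degrees, origins in Å, defocus in
Å) plus an equivalent CSV, so real refinement outputs can be fed to the
multi-run diagnostics.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .forward import ParticleStack
from .geometry import Pose
from .volume import Volume

REQUIRED_COLUMNS = ("rlnImageName", "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi",
                    "rlnOriginXAngst", "rlnOriginYAngst", "rlnDefocusU",
                    "rlnDefocusV", "rlnClassNumber")


def write_volume(volume: Volume, path) -> None:
    """Write an MRC2014 map (mode 2 float, cubic cell, voxel size in header)."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data, dtype=np.float32))
    a = volume.box * volume.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(a, a, a, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_volume(path) -> Volume:
    """Read an MRC2014 map; only cubic single-volume maps are supported."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed MRC file {path}: {exc}") from exc
    data = np.array(m.grid, copy=True).astype(np.float64)
    if data.ndim != 3 or len(set(data.shape)) != 1:
        raise ValueError(f"non-cubic volume not supported: shape {data.shape}")
    nx = data.shape[0]
    voxel = m.grid.unit_cell.a / nx
    if voxel <= 0:
        raise ValueError("malformed MRC header: non-positive cell dimension 'a'")
    return Volume(data, float(voxel))


def write_image_stack(images: np.ndarray, voxel_size: float, path) -> None:
    """Write a stack of square images as an MRC volume (nz = n images)."""
    arr = np.ascontiguousarray(images, dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    nz, ny, nx = arr.shape
    m.grid.unit_cell = gemmi.UnitCell(nz * voxel_size, ny * voxel_size,
                                      nx * voxel_size, 90.0, 90.0, 90.0)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_image_stack(path) -> tuple[np.ndarray, float]:
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True).astype(np.float64)
    voxel = m.grid.unit_cell.b / data.shape[1]
    return data, float(voxel)


def stack_to_table(stack: ParticleStack, image_name: str = "stack.mrcs") -> pd.DataFrame:
    """Per-particle metadata table in STAR column conventions.

    Shifts are exported in Å (pixels * pixel size); defocus U/V both carry
    the nominal defocus (no astigmatism in the forward model).
    """
    rows = []
    for i in range(len(stack)):
        p = stack.truth_poses[i]
        c = stack.ctf_nominal[i]
        rows.append({
            "rlnImageName": f"{i + 1:06d}@{image_name}",
            "rlnAngleRot": p.rot,
            "rlnAngleTilt": p.tilt,
            "rlnAnglePsi": p.psi,
            "rlnOriginXAngst": p.shift_x * stack.voxel_size,
            "rlnOriginYAngst": p.shift_y * stack.voxel_size,
            "rlnDefocusU": c.defocus_A,
            "rlnDefocusV": c.defocus_A,
            "rlnClassNumber": int(stack.truth_class[i]) + 1,
        })
    return pd.DataFrame(rows)


def write_particles_star(table: pd.DataFrame, path) -> None:
    """Write a data_particles STAR loop."""
    _check_columns(table)
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    loop = block.init_loop("_", list(table.columns))
    for _, row in table.iterrows():
        loop.add_row([_star_value(v) for v in row])
    doc.write_file(str(path))


def _star_value(v) -> str:
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)


def read_particles_star(path) -> pd.DataFrame:
    doc = gemmi.cif.read_file(str(path))
    block = doc[0]
    first_loop = None
    for item in block:
        if item.loop is not None:
            first_loop = item.loop
            break
    if first_loop is None:
        raise ValueError(f"no loop found in STAR file {path}")
    tags = [t.lstrip("_") for t in first_loop.tags]
    vals = np.array(first_loop.values, dtype=object).reshape(first_loop.length(),
                                                             first_loop.width())
    table = pd.DataFrame({tag: vals[:, j] for j, tag in enumerate(tags)})
    for col in table.columns:
        if col != "rlnImageName":
            table[col] = pd.to_numeric(table[col], errors="coerce")
    _check_columns(table)
    return table


def write_particles_csv(table: pd.DataFrame, path) -> None:
    _check_columns(table)
    table.to_csv(path, index=False)


def read_particles_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    _check_columns(table)
    return table


def _check_columns(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing required column: {col}")


def table_to_poses(table: pd.DataFrame, voxel_size: float) -> list[Pose]:
    """Poses from a particle table; Å origins are converted back to pixels."""
    return [Pose(float(r.rlnAngleRot), float(r.rlnAngleTilt), float(r.rlnAnglePsi),
                 float(r.rlnOriginXAngst) / voxel_size,
                 float(r.rlnOriginYAngst) / voxel_size)
            for r in table.itertuples()]


def write_json_report(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)
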