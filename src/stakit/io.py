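"""MRC2014 volume I/O (via gemmi) and particle-table I/O.

Volumes are written as MRC mode 2 (32-bit float) with the voxel size in the
cell header and the physical origin in header words 50–52; both survive a
round trip.  Particle tables are plain tab-separated text with a fixed
column schema; angles are Z–X–Z degrees, positions and shifts are Å
(0-based voxel origin, x the fastest axis).
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .volume import DensityVolume


class FormatError(ValueError):
    """Unreadable or unsupported file content."""


def read_volume(path: str | Path) -> DensityVolume:
    """Read an MRC2014 map into a :class:`DensityVolume`."""
    path = Path(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read MRC map {path}: {exc}") from None
    grid = m.grid
    data = np.array(grid, copy=True)
    if grid.nu != grid.nv or grid.nv != grid.nw:
        raise FormatError(f"non-cubic map {path}: {grid.nu}x{grid.nv}x{grid.nw}")
    voxel = grid.unit_cell.a / grid.nu
    origin = tuple(float(m.header_float(w)) for w in (50, 51, 52))
    return DensityVolume(data.astype(np.float32), voxel, origin)


def write_volume(vol: DensityVolume, path: str | Path) -> None:
    """Write a :class:`DensityVolume` as an MRC2014 mode-2 map."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid = gemmi.FloatGrid(np.ascontiguousarray(vol.data, dtype=np.float32))
    extent = vol.box * vol.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(extent, extent, extent, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, val in zip((50, 51, 52), vol.origin):
        m.set_header_float(w, float(val))
    m.write_ccp4_map(str(path))


PARTICLE_COLUMNS = [
    "id",
    "x",
    "y",
    "z",
    "tdrot",
    "tilt",
    "narot",
    "dx",
    "dy",
    "dz",
    "cc",
    "class_id",
    "halfset",
]

_DTYPES = {
    "id": np.int64,
    "class_id": np.int64,
    "halfset": str,
    **{c: float for c in ("x", "y", "z", "tdrot", "tilt", "narot", "dx", "dy", "dz", "cc")},
}


def empty_particle_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in PARTICLE_COLUMNS})


def validate_particle_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"particle table is missing mandatory columns: {missing}")
    df = df[PARTICLE_COLUMNS].copy()
    for c, dt in _DTYPES.items():
        df[c] = df[c].astype(dt)
    if len(df) and not ((df["cc"] >= -1.0) & (df["cc"] <= 1.0)).all():
        raise FormatError("cc values outside [-1, 1]")
    if len(df) and not df["halfset"].isin(["A", "B", "-"]).all():
        raise FormatError("halfset labels must be A, B or '-' (unassigned)")
    return df


def read_particle_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated particle table, validating the schema."""
    df = pd.read_csv(path, sep="\t", dtype={"halfset": str})
    return validate_particle_table(df)


def write_particle_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validate_particle_table(df).to_csv(path, sep="\t", index=False, float_format="%.6g")
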