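"""File I/O: MRC/CCP4 maps and stacks (via gemmi), STAR/CSV metadata, PDB export.

Maps are written as mode-2 float MRC with the voxel size encoded in the
unit cell.  Metadata tables are pandas DataFrames, written either as CSV
or as a minimal single-data-block STAR file (one ``loop_``, named
columns); STAR support is intentionally small — one block, one loop.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd

from .core import ValidationError, VolumeMap

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_star",
    "read_star",
    "write_table",
    "read_table",
    "atoms_to_pdb",
]


def write_mrc(path: str | os.PathLike, data: np.ndarray, voxel_size: float) -> None:
    """Write a 2D image, 3D volume or stack as a float32 MRC/CCP4 map."""
    arr = np.ascontiguousarray(np.asarray(data), dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValidationError("write_mrc expects a 2D or 3D array")
    grid = gemmi.FloatGrid(arr)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    grid.set_unit_cell(
        gemmi.UnitCell(
            arr.shape[0] * voxel_size,
            arr.shape[1] * voxel_size,
            arr.shape[2] * voxel_size,
            90.0, 90.0, 90.0,
        )
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path: str | os.PathLike) -> VolumeMap:
    """Read an MRC/CCP4 map; returns a VolumeMap (stacks keep frame axis first)."""
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True)
    voxel = m.grid.unit_cell.a / m.grid.nu
    return VolumeMap(data.astype(np.float64), float(voxel))


def write_star(df: pd.DataFrame, path: str | os.PathLike, block: str = "particles") -> None:
    """Write a DataFrame as a single-block STAR loop (columns prefixed '_')."""
    lines = [f"data_{block}", "", "loop_"]
    for i, col in enumerate(df.columns, start=1):
        lines.append(f"_{col} #{i}")
    for _, row in df.iterrows():
        lines.append(" ".join(_star_token(v) for v in row))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _star_token(v) -> str:
    if isinstance(v, float):
        return f"{v:.6f}"
    s = str(v)
    return s if s and " " not in s else f'"{s}"'


def read_star(path: str | os.PathLike) -> pd.DataFrame:
    """Read a single-loop STAR file back into a DataFrame."""
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                continue
            if in_loop and line.startswith("_"):
                cols.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and cols:
                rows.append(line.split())
    if not cols:
        raise ValidationError(f"no STAR loop found in {path}")
    df = pd.DataFrame(rows, columns=cols)
    for c in df.columns:
        converted = pd.to_numeric(df[c], errors="coerce")
        if not converted.isna().any():
            df[c] = converted
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write metadata as STAR or CSV depending on the file extension."""
    p = str(path)
    if p.endswith(".star"):
        write_star(df, p)
    else:
        df.to_csv(p, index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    p = str(path)
    if p.endswith(".star"):
        return read_star(p)
    return pd.read_csv(p)


def atoms_to_pdb(atoms, path: str | os.PathLike) -> None:
    """Export pseudo-atoms as one-HETATM-per-blob PDB for external viewers.

    ``atoms`` is an iterable of (x, y, z, weight, sigma) in Angstrom; the
    Gaussian width goes into the B-factor column, the weight into occupancy
    (clipped to the PDB's [0, 1] field).
    """
    st = gemmi.Structure()
    st.name = "phantom"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (x, y, z, w, sigma) in enumerate(atoms, start=1):
        res = gemmi.Residue()
        res.name = "DUM"
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "H"
        at = gemmi.Atom()
        at.name = "C"
        at.element = gemmi.Element("C")
        at.pos = gemmi.Position(float(x), float(y), float(z))
        at.occ = float(min(1.0, max(0.0, w)))
        at.b_iso = float(sigma)
        res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
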