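"""Grid, table and configuration I/O.

3-D grids travel as NRRD or MetaImage (MHD/MHA) through SimpleITK, losslessly
round-tripping values, spacing and origin; the quantity tag is stored as a
header key-value where the format supports it (NRRD).  LEM tables are CSV
with columns ``let_kev_um,alpha_gy-1,beta_gy-2`` (or ``energy_mev`` as the
first column together with a caller-supplied converter); tissue sets are
JSON objects {"name", "alpha_x", "beta_x", "d_t"}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .grids import ScalarGrid, StructureMask
from .models import LEMTable, TissueParams

__all__ = [
    "read_grid",
    "write_grid",
    "read_mask",
    "write_mask",
    "read_lem_table_csv",
    "write_lem_table_csv",
    "read_tissue_json",
    "write_tissue_json",
    "GridFormatError",
]

_EXTENSIONS = (".nrrd", ".mhd", ".mha")
_QUANTITY_KEY = "protonrbe_quantity"


class GridFormatError(ValueError):
    """A grid file could not be read or has unsupported structure."""


def _check_extension(path: Path) -> None:
    if path.suffix.lower() not in _EXTENSIONS:
        raise GridFormatError(
            f"unknown grid file extension {path.suffix!r} for {path.name}; "
            f"expected one of {', '.join(_EXTENSIONS)}"
        )


def write_grid(path, grid: ScalarGrid) -> None:
    """Write a grid as NRRD (uncompressed) or MetaImage, axis order preserved.

    The array's (i, j, k) indices map to the image's (x, y, z); SimpleITK
    stores arrays as (z, y, x), so the values are transposed on the way out
    and back, which round-trips bit-exactly.
    """
    path = Path(path)
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    img.SetMetaData(_QUANTITY_KEY, grid.quantity)
    sitk.WriteImage(img, str(path), useCompression=False)


def read_grid(path, quantity: str | None = None) -> ScalarGrid:
    """Read an NRRD/MetaImage grid; ``quantity`` overrides the stored tag."""
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise GridFormatError(f"grid file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise GridFormatError(f"cannot read {path.name}: {exc}") from exc
    if img.GetDimension() != 3:
        raise GridFormatError(
            f"{path.name}: expected a 3-D grid, found dimension {img.GetDimension()}"
        )
    values = sitk.GetArrayFromImage(img).T
    tag = quantity
    if tag is None:
        tag = (img.GetMetaData(_QUANTITY_KEY)
               if img.HasMetaDataKey(_QUANTITY_KEY) else "dose_gy")
    return ScalarGrid(values=values, spacing=tuple(img.GetSpacing()),
                      origin=tuple(img.GetOrigin()), quantity=tag)


def write_mask(path, mask: StructureMask, like: ScalarGrid | None = None) -> None:
    """Write a structure mask as a uint8 grid."""
    path = Path(path)
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(mask.mask.T.astype(np.uint8)))
    if like is not None:
        img.SetSpacing(tuple(float(s) for s in like.spacing))
        img.SetOrigin(tuple(float(o) for o in like.origin))
    img.SetMetaData(_QUANTITY_KEY, f"mask_{mask.label}")
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mask(path, label: str = "PTV") -> StructureMask:
    path = Path(path)
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    return StructureMask(sitk.GetArrayFromImage(img).T.astype(bool), label)


def read_lem_table_csv(path) -> LEMTable:
    """Read a LET-keyed LEM alpha/beta table from CSV."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "let_kev_um" not in cols:
        raise ValueError(
            f"LEM table {path} must have a 'let_kev_um' column "
            "(energy-keyed tables must be converted to LET upstream); "
            f"found columns {list(df.columns)}"
        )
    try:
        alpha_col = cols["alpha_gy-1"]
        beta_col = cols["beta_gy-2"]
    except KeyError as exc:
        raise ValueError(f"LEM table {path} missing column {exc}") from exc
    return LEMTable(df[cols["let_kev_um"]].to_numpy(),
                    df[alpha_col].to_numpy(), df[beta_col].to_numpy())


def write_lem_table_csv(path, table: LEMTable) -> None:
    pd.DataFrame({
        "let_kev_um": table.let,
        "alpha_gy-1": table.alpha,
        "beta_gy-2": table.beta,
    }).to_csv(path, index=False)


def read_tissue_json(path) -> TissueParams:
    with open(path) as fh:
        obj = json.load(fh)
    return TissueParams(alpha_x=obj["alpha_x"], beta_x=obj["beta_x"],
                        d_t=obj.get("d_t"), name=obj.get("name", ""))


def write_tissue_json(path, tissue: TissueParams) -> None:
    with open(path, "w") as fh:
        json.dump({"name": tissue.name, "alpha_x": tissue.alpha_x,
                   "beta_x": tissue.beta_x, "d_t": tissue.d_t}, fh, indent=2)
        fh.write("\n")
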