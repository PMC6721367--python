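"""Lightweight writers: legacy-VTK structured grids and cutline CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .diffusion import CutlineProfile
from .errors import GeometryError
from .phantom import Phantom


def write_vtk(path, phantom: Phantom, fields: dict) -> None:
    """Write per-cell scalar fields as a legacy ASCII VTK structured-points file.

    Axisymmetric grids are written as (nr, nz, 1) planes; voxel grids as-is.
    Cell data order follows VTK's x-fastest convention.
    """
    if phantom.grid_kind == "slab_1d":
        dims = (phantom.shape[0] + 1, 2, 2)
        reorder = lambda a: a[:, None, None]
    elif phantom.grid_kind == "axisymmetric_2d":
        dims = (phantom.shape[0] + 1, phantom.shape[1] + 1, 2)
        reorder = lambda a: a[:, :, None]
    elif phantom.grid_kind == "voxel_3d":
        dims = tuple(n + 1 for n in phantom.shape)
        reorder = lambda a: a
    else:
        raise GeometryError(f"cannot export grid kind {phantom.grid_kind!r}")

    n_cells = int(np.prod([d - 1 for d in dims]))
    h = phantom.spacing
    lines = [
        "# vtk DataFile Version 3.0",
        "tnirsim structured field export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
        "ORIGIN 0 0 0",
        f"SPACING {h} {h} {h}",
        f"CELL_DATA {n_cells}",
    ]
    for name, arr in fields.items():
        a = reorder(np.asarray(arr, dtype=float))
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK iterates x fastest, z slowest
        flat = np.transpose(a, (2, 1, 0)).ravel()
        lines.extend(" ".join(f"{v:.8e}" for v in flat[i : i + 6])
                     for i in range(0, flat.size, 6))
    Path(path).write_text("\n".join(lines) + "\n")


def write_cutline_csv(path, profile: CutlineProfile, value_name: str = "value",
                      extra: dict | None = None) -> None:
    """Write a cutline profile as CSV (depth_m, tissue, <value>, extras)."""
    df = profile.to_dataframe().rename(columns={"value": value_name})
    for name, col in (extra or {}).items():
        df[name] = np.asarray(col)
    df.to_csv(path, index=False)
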