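"""File I/O: snapshot container, VTK export, CSV profiles, JSON reports.

Snapshots use an HDF5 container with named field arrays and a metadata
header (grid spec, physics parameters, arc-length position).  For
visualization, fields can additionally be exported as ASCII legacy-VTK
rectilinear grids readable by ParaView/VisIt.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .grid import AxisymGrid, build_grid
from .mep import MEPResult

__all__ = [
    "save_snapshot",
    "load_snapshot",
    "write_vtk_rectilinear",
    "mep_to_dataframe",
    "write_mep_csv",
    "write_extrema_json",
]


def save_snapshot(
    path: str | Path,
    grid: AxisymGrid,
    fields: dict[str, np.ndarray],
    meta: dict | None = None,
) -> None:
    """Write named field arrays plus grid/metadata attributes."""
    with h5py.File(path, "w") as h5:
        gr = h5.create_group("grid")
        for key in ("nr", "nz", "r_max", "z_min", "z_max"):
            gr.attrs[key] = getattr(grid, key)
        fg = h5.create_group("fields")
        for name, arr in fields.items():
            fg.create_dataset(name, data=grid.check(arr))
        mg = h5.create_group("meta")
        for key, val in (meta or {}).items():
            mg.attrs[key] = val


def load_snapshot(
    path: str | Path,
) -> tuple[AxisymGrid, dict[str, np.ndarray], dict]:
    """Read a snapshot back; fields round-trip bit-identically."""
    with h5py.File(path, "r") as h5:
        ga = h5["grid"].attrs
        grid = build_grid(
            int(ga["nr"]), int(ga["nz"]),
            float(ga["r_max"]), float(ga["z_min"]), float(ga["z_max"]),
        )
        fields = {name: ds[...] for name, ds in h5["fields"].items()}
        meta = dict(h5["meta"].attrs)
    return grid, fields, meta


def write_vtk_rectilinear(
    path: str | Path, grid: AxisymGrid, fields: dict[str, np.ndarray]
) -> None:
    """ASCII legacy-VTK rectilinear grid (r, z, 1) with point scalars."""
    lines = [
        "# vtk DataFile Version 3.0",
        "fusefield axisymmetric field snapshot",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {grid.nr} {grid.nz} 1",
        f"X_COORDINATES {grid.nr} double",
        " ".join(f"{x:.10g}" for x in grid.r_centers),
        f"Y_COORDINATES {grid.nz} double",
        " ".join(f"{x:.10g}" for x in grid.z_centers),
        "Z_COORDINATES 1 double",
        "0",
        f"POINT_DATA {grid.nr * grid.nz}",
    ]
    for name, arr in fields.items():
        arr = grid.check(arr)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK varies x (here r) fastest
        lines.extend(
            " ".join(f"{v:.10g}" for v in arr[:, j]) for j in range(grid.nz)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def mep_to_dataframe(result: MEPResult) -> pd.DataFrame:
    """One row per image: index, alpha, energy breakdown, dE."""
    rows = []
    for i, rep in enumerate(result.reports):
        rows.append(
            {
                "index": i,
                "alpha": result.alpha[i],
                "E_B": rep.E_B,
                "E_G": rep.E_G,
                "E_A": rep.E_A,
                "E": rep.E,
                "dE": result.dE[i],
                "A": rep.A,
                "V": rep.V,
                "P": rep.P,
            }
        )
    return pd.DataFrame(rows)


def write_mep_csv(path: str | Path, result: MEPResult) -> None:
    mep_to_dataframe(result).to_csv(path, index=False)


def write_extrema_json(path: str | Path, result: MEPResult) -> None:
    """Extrema summary (minima, saddles, barriers) as structured JSON."""
    payload = {
        "minima": [{"index": i, "alpha": a, "dE": float(result.dE[i])}
                   for i, a in result.minima],
        "saddles": [{"index": i, "alpha": a, "dE": float(result.dE[i])}
                    for i, a in result.saddles],
        "barriers": result.barriers,
        "principal_barrier": result.principal_barrier,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
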