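"""Legacy-ASCII VTK rectilinear-grid writer for cell-centered fields."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_rectilinear_vtk(
    path: str | Path,
    x_edges: np.ndarray,
    y_edges: np.ndarray,
    cell_data: dict[str, np.ndarray],
    z_edges: np.ndarray | None = None,
    title: str = "lobuleflow field",
) -> Path:
    """Write 2-D cell data on a rectilinear grid as a legacy-ASCII VTK file.

    ``cell_data`` maps array names to (ny, nx) arrays indexed [row=y,
    col=x]; a single cell layer in z is written (thickness from
    ``z_edges`` or unit).  Row-major flattening matches VTK's
    x-fastest cell ordering.
    """
    path = Path(path)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    if z_edges is None:
        z_edges = np.array([0.0, 1.0])
    nx, ny = len(x_edges) - 1, len(y_edges) - 1

    def coord_block(name: str, arr: np.ndarray) -> str:
        vals = " ".join(f"{v:.9g}" for v in arr)
        return f"{name}_COORDINATES {len(arr)} float\n{vals}\n"

    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx + 1} {ny + 1} {len(z_edges)}",
    ]
    body = "\n".join(lines) + "\n"
    body += coord_block("X", x_edges)
    body += coord_block("Y", y_edges)
    body += coord_block("Z", z_edges)
    body += f"CELL_DATA {nx * ny * (len(z_edges) - 1)}\n"
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if arr.shape != (ny, nx):
            raise ValueError(f"cell array {name!r} has shape {arr.shape}, expected {(ny, nx)}")
        if " " in name:
            raise ValueError(f"VTK array names cannot contain spaces: {name!r}")
        body += f"SCALARS {name} float 1\nLOOKUP_TABLE default\n"
        flat = arr.ravel(order="C")  # x fastest
        body += "\n".join(" ".join(f"{v:.9g}" for v in flat[k:k + 9])
                          for k in range(0, len(flat), 9)) + "\n"
    path.write_text(body)
    return path
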