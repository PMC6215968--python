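"""Minimal legacy-ASCII VTK unstructured-grid writer.

Writes triangle meshes with point data (potentials, activation times) and
cell data (region labels, fiber vectors) for inspection in ParaView.
Only the small subset of the legacy format needed here is implemented.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .strand_geometry import TissueMesh

__all__ = ["write_vtk"]


def _write_array(fh, name: str, arr: np.ndarray) -> None:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 1:
        fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, np.nan_to_num(arr, nan=-1e30), fmt="%.9g")
    else:
        comps = np.zeros((len(arr), 3))
        comps[:, : arr.shape[1]] = np.nan_to_num(arr, nan=0.0)
        fh.write(f"VECTORS {name} double\n")
        np.savetxt(fh, comps, fmt="%.9g")


def write_vtk(
    path: str | Path,
    mesh: TissueMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "endocv strand",
) -> Path:
    """Write the mesh and optional fields to a legacy VTK file."""
    path = Path(path)
    tris = mesh.triangles
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        xyz = np.column_stack([mesh.nodes, np.zeros(mesh.n_nodes)])
        np.savetxt(fh, xyz, fmt="%.9g")
        fh.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        np.savetxt(
            fh, np.column_stack([np.full(len(tris), 3), tris]), fmt="%d"
        )
        fh.write(f"CELL_TYPES {len(tris)}\n")
        np.savetxt(fh, np.full(len(tris), 5), fmt="%d")  # VTK_TRIANGLE

        point_data = dict(point_data or {})
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                _write_array(fh, name, arr)
        cell_data = dict(cell_data or {})
        cell_data.setdefault("region", mesh.region.astype(float))
        fh.write(f"CELL_DATA {len(tris)}\n")
        for name, arr in cell_data.items():
            _write_array(fh, name, arr)
    return path
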