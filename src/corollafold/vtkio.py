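"""Minimal legacy ASCII VTK export of triangle meshes with field data.

Writes DATASET UNSTRUCTURED_GRID files (VTK legacy format 2.0, 0-based
indices, triangle cell type 5) with optional POINT_DATA vectors and
CELL_DATA scalars — enough for ParaView/VTK-based inspection of growth
snapshots and stress maps.
"""

from __future__ import annotations

import numpy as np

from .geometry import TriMesh

__all__ = ["write_vtk"]


def write_vtk(mesh: TriMesh, path, point_vectors: dict | None = None,
              cell_scalars: dict | None = None, title: str = "corollafold") -> None:
    """Write the mesh and fields as a legacy ASCII VTK unstructured grid.

    point_vectors: name -> (N, 2) arrays written as 3D vectors (z=0).
    cell_scalars: name -> (M,) arrays written as float scalars.
    """
    n, m = len(mesh.nodes), len(mesh.triangles)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# vtk DataFile Version 2.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for x, y in mesh.nodes:
            fh.write(f"{x:.12g} {y:.12g} 0\n")
        fh.write(f"CELLS {m} {4 * m}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("5\n" * m)
        if point_vectors:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in point_vectors.items():
                arr = np.asarray(arr)
                fh.write(f"VECTORS {name} double\n")
                for vx, vy in arr:
                    fh.write(f"{vx:.12g} {vy:.12g} 0\n")
        if cell_scalars:
            fh.write(f"CELL_DATA {m}\n")
            for name, arr in cell_scalars.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    fh.write(f"{v:.12g}\n")
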