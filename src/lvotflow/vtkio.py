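"""Minimal legacy-ASCII VTK unstructured-grid writer/reader for snapshots."""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk", "read_vtk"]


def write_vtk(path, points: np.ndarray, tris: np.ndarray,
              point_data: dict) -> None:
    """Write a 2D triangle mesh with nodal fields as legacy ASCII VTK."""
    n = len(points)
    m = len(tris)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlvotflow snapshot\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        for x, y in points:
            fh.write(f"{x:.10e} {y:.10e} 0.0\n")
        fh.write(f"CELLS {m} {4 * m}\n")
        for a, b, c in tris:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["5"] * m) + "\n")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                fh.write(f"VECTORS {name} double\n")
                for vx, vy in arr:
                    fh.write(f"{vx:.10e} {vy:.10e} 0.0\n")
            else:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    fh.write(f"{v:.10e}\n")


def read_vtk(path):
    """Read a file written by :func:`write_vtk`.

    Returns (points, tris, point_data).
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0
    points = tris = None
    data = {}
    n = m = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = [tokens[i + 1 + k].split() for k in range(n)]
            points = np.asarray(vals, float)[:, :2]
            i += n
        elif line.startswith("CELLS"):
            m = int(line.split()[1])
            vals = [tokens[i + 1 + k].split()[1:] for k in range(m)]
            tris = np.asarray(vals, int)
            i += m
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            vals = [tokens[i + 1 + k].split() for k in range(n)]
            data[name] = np.asarray(vals, float)[:, :2]
            i += n
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            vals = [tokens[i + 2 + k] for k in range(n)]
            data[name] = np.asarray(vals, float)
            i += n + 1
        i += 1
    if points is None or tris is None:
        raise ValueError(f"{path} is not a recognizable VTK snapshot")
    return points, tris, data
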