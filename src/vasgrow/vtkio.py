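"""Minimal legacy-ASCII VTK readers/writers for tet meshes and polylines.

Covers exactly what the package exchanges with visualization tools: an
unstructured grid of tetrahedra with CELL_DATA scalars (demand, density,
owner, tissue flow, pressure) and a polydata of vessel polylines with
radius/flow/pressure data arrays.  Text format only.
"""

from __future__ import annotations

import numpy as np

VTK_TETRA = 10


def write_unstructured_grid(path, vertices: np.ndarray, elements: np.ndarray,
                            cell_data: dict[str, np.ndarray] | None = None,
                            point_data: dict[str, np.ndarray] | None = None) -> None:
    vertices = np.asarray(vertices, float)
    elements = np.asarray(elements, np.int64)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvasgrow tissue mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(vertices)} double\n")
        np.savetxt(f, vertices, fmt="%.17g")
        n = len(elements)
        f.write(f"CELLS {n} {5 * n}\n")
        np.savetxt(f, np.column_stack([np.full(n, 4), elements]), fmt="%d")
        f.write(f"CELL_TYPES {n}\n")
        np.savetxt(f, np.full(n, VTK_TETRA), fmt="%d")
        if cell_data:
            f.write(f"CELL_DATA {n}\n")
            _write_data_arrays(f, cell_data)
        if point_data:
            f.write(f"POINT_DATA {len(vertices)}\n")
            _write_data_arrays(f, point_data)


def _write_data_arrays(f, arrays: dict[str, np.ndarray]) -> None:
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        if arr.ndim == 2 and arr.shape[1] == 3:
            f.write(f"VECTORS {name} double\n")
            np.savetxt(f, arr, fmt="%.17g")
        else:
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, arr.reshape(-1, 1), fmt="%.17g")


def read_unstructured_grid(path):
    """Read a legacy ASCII unstructured grid of tetrahedra.

    Returns (vertices, elements, cell_data) where cell_data maps array name
    to a 1-D float array.
    """
    with open(path) as f:
        tokens = f.read().split()
    it = iter(range(len(tokens)))
    pos = 0

    def expect(word):
        nonlocal pos
        while pos < len(tokens) and tokens[pos].upper() != word:
            pos += 1
        if pos >= len(tokens):
            raise ValueError(f"malformed VTK file {path}: missing {word}")
        pos += 1

    expect("DATASET")
    if tokens[pos].upper() != "UNSTRUCTURED_GRID":
        raise ValueError(f"{path}: not an unstructured grid")
    expect("POINTS")
    n_pts = int(tokens[pos]); pos += 2  # count, dtype
    verts = np.array(tokens[pos:pos + 3 * n_pts], float).reshape(n_pts, 3)
    pos += 3 * n_pts
    expect("CELLS")
    n_cells = int(tokens[pos]); total = int(tokens[pos + 1]); pos += 2
    raw = np.array(tokens[pos:pos + total], np.int64)
    pos += total
    if not np.all(raw.reshape(n_cells, -1)[:, 0] == 4):
        raise ValueError(f"{path}: only tetrahedral cells supported")
    elements = raw.reshape(n_cells, 5)[:, 1:]
    cell_data: dict[str, np.ndarray] = {}
    # optional CELL_DATA section with SCALARS entries
    while pos < len(tokens):
        if tokens[pos].upper() == "CELL_DATA":
            pos += 2
            while pos < len(tokens) and tokens[pos].upper() == "SCALARS":
                name = tokens[pos + 1]
                pos += 4  # SCALARS name dtype ncomp
                if tokens[pos].upper() == "LOOKUP_TABLE":
                    pos += 2
                cell_data[name] = np.array(tokens[pos:pos + n_cells], float)
                pos += n_cells
            continue
        pos += 1
    return verts, elements, cell_data


def write_forest_polydata(path, forest, segment_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a vascular forest as VTK polydata lines with per-segment data."""
    segs = sorted(forest.segments.values(), key=lambda s: s.id)
    pts = np.vstack([[s.proximal, s.distal] for s in segs]).reshape(-1, 3)
    n_seg = len(segs)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvasgrow vessel network\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(pts)} double\n")
        np.savetxt(f, pts, fmt="%.17g")
        f.write(f"LINES {n_seg} {3 * n_seg}\n")
        conn = np.column_stack([np.full(n_seg, 2),
                                np.arange(0, 2 * n_seg, 2),
                                np.arange(1, 2 * n_seg + 1, 2)])
        np.savetxt(f, conn, fmt="%d")
        data = {"radius": np.array([s.radius for s in segs]),
                "flow": np.array([s.flow for s in segs])}
        if segment_data:
            data.update(segment_data)
        f.write(f"CELL_DATA {n_seg}\n")
        _write_data_arrays(f, data)
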