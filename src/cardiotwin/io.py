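"""Plain-text export helpers: ASCII VTU (unstructured-grid XML) for
meshes, fields and Purkinje polylines, plus JSON electrode sets.

The VTU writer emits the minimal ASCII subset every VTK-compatible viewer
reads; fields are float64, cells are tetrahedra (type 10) or line
segments (type 3)."""

from __future__ import annotations

import json

import numpy as np


def _data_array(name, data, n_components=1, dtype="Float64"):
    flat = np.asarray(data).reshape(-1)
    if dtype.startswith("Float"):
        body = " ".join(f"{v:.9g}" for v in flat)
    else:
        body = " ".join(str(int(v)) for v in flat)
    nc = f' NumberOfComponents="{n_components}"' if n_components != 1 else ""
    nm = f' Name="{name}"' if name else ""
    return f'<DataArray type="{dtype}"{nm}{nc} format="ascii">{body}</DataArray>'


def _write_vtu(path, points, cells, cell_type, point_data=None, cell_data=None):
    points = np.asarray(points, float)
    cells = np.asarray(cells, int)
    n_pts, n_cells = len(points), len(cells)
    per_cell = cells.shape[1]
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "<Points>",
        _data_array(None, points, 3),
        "</Points>",
        "<Cells>",
        _data_array("connectivity", cells, dtype="Int64"),
        _data_array("offsets", np.arange(1, n_cells + 1) * per_cell, dtype="Int64"),
        _data_array("types", np.full(n_cells, cell_type), dtype="UInt8"),
        "</Cells>",
    ]
    if point_data:
        parts.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            nc = arr.shape[1] if arr.ndim == 2 else 1
            parts.append(_data_array(name, arr, nc))
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            nc = arr.shape[1] if arr.ndim == 2 else 1
            parts.append(_data_array(name, arr, nc))
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    with open(path, "w") as f:
        f.write("\n".join(parts))


def write_mesh_vtu(path, mesh, point_data=None, cell_data=None):
    """Tetrahedral mesh with optional nodal (e.g. the transmural
    coordinate, potentials, maps) and per-tet (e.g. fibers) fields."""
    _write_vtu(path, mesh.vertices, mesh.tets, 10, point_data, cell_data)


def write_purkinje_vtu(path, network):
    """Purkinje network as line cells, bundle id as cell data (0 left,
    1 right) and PMJ flag as point data."""
    bundle = (network.edge_bundle == "RIGHT").astype(int)
    pmj = np.zeros(len(network.nodes))
    pmj[network.pmj_nodes] = 1.0
    _write_vtu(path, network.nodes, network.edges, 3,
               point_data={"pmj": pmj}, cell_data={"bundle": bundle})


def write_electrodes_json(path, electrodes):
    with open(path, "w") as f:
        json.dump({k: list(map(float, v)) for k, v in electrodes.positions.items()}, f, indent=1)


def read_electrodes_json(path):
    from cardiotwin.anatomy import ElectrodeSet

    with open(path) as f:
        d = json.load(f)
    return ElectrodeSet({k: np.asarray(v, float) for k, v in d.items()})
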