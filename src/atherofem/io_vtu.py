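"""Minimal ASCII VTU (VTK XML unstructured grid) export/import.

Covers linear quads/hexes with point and cell data, plus polyline export for
vasa-vasorum trees.  The reader handles the subset this writer produces
(round-trip of our own meshes), not arbitrary VTK files.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

_VTK_QUAD = 9
_VTK_HEX = 12
_VTK_LINE = 3


def _data_array(name: str, arr: np.ndarray, n_comp: int | None = None) -> str:
    arr = np.asarray(arr)
    if arr.dtype.kind in "iu":
        typ = "Int64"
        fmt = "%d"
    else:
        typ = "Float64"
        fmt = "%.16g"
    comp = f' NumberOfComponents="{n_comp}"' if n_comp else ""
    flat = arr.reshape(-1)
    body = " ".join(fmt % v for v in flat)
    return (f'<DataArray type="{typ}" Name="{name}"{comp} format="ascii">'
            f"{body}</DataArray>")


def write_vtu(path, points: np.ndarray, cells: np.ndarray, cell_type: int | None = None,
              point_data: dict | None = None, cell_data: dict | None = None) -> None:
    """Write one unstructured grid; 2D points are padded with z=0."""
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    cells = np.asarray(cells, dtype=np.int64)
    if cell_type is None:
        cell_type = {2: _VTK_LINE, 4: _VTK_QUAD, 8: _VTK_HEX}[cells.shape[1]]
    n_cells, npc = cells.shape
    offsets = np.arange(1, n_cells + 1) * npc
    types = np.full(n_cells, cell_type)

    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             "<UnstructuredGrid>",
             f'<Piece NumberOfPoints="{len(points)}" NumberOfCells="{n_cells}">',
             "<Points>", _data_array("Points", points, 3), "</Points>",
             "<Cells>",
             _data_array("connectivity", cells),
             _data_array("offsets", offsets),
             _data_array("types", types),
             "</Cells>"]
    if point_data:
        parts.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            nc = arr.shape[1] if arr.ndim == 2 else None
            if nc == 2:  # pad vectors for VTK
                arr = np.column_stack([arr, np.zeros(len(arr))])
                nc = 3
            parts.append(_data_array(name, arr, nc))
        parts.append("</PointData>")
    if cell_data:
        parts.append("<CellData>")
        for name, arr in cell_data.items():
            parts.append(_data_array(name, np.asarray(arr)))
        parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def write_mesh(path, mesh, point_data=None, cell_data=None) -> None:
    """Export a :class:`~atherofem.geometry.Mesh`; tags become integer cell data."""
    cd = dict(cell_data or {})
    for name, ids in mesh.element_tags.items():
        marker = np.zeros(mesh.n_elements, dtype=np.int64)
        marker[ids] = 1
        cd[name] = marker
    write_vtu(path, mesh.node_coords, mesh.elements,
              point_data=point_data, cell_data=cd)


def write_trees(path, trees) -> None:
    """Export fractal trees as VTK line cells with a per-segment level array."""
    pts, lines, levels = [], [], []
    off = 0
    for t in trees:
        for p, q, lev in zip(t.starts, t.ends, t.levels):
            p3 = np.append(p, 0.0)[:3] if len(p) == 2 else p
            q3 = np.append(q, 0.0)[:3] if len(q) == 2 else q
            pts += [p3, q3]
            lines.append([off, off + 1])
            levels.append(lev)
            off += 2
    if not pts:
        pts = [np.zeros(3)]
        lines = []
    write_vtu(path, np.asarray(pts), np.asarray(lines, dtype=np.int64).reshape(-1, 2),
              cell_type=_VTK_LINE,
              cell_data={"level": np.asarray(levels, dtype=np.int64)} if levels else None)


def read_vtu(path):
    """Read points, connectivity and data written by :func:`write_vtu`."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")

    def parse(elem):
        txt = (elem.text or "").split()
        if elem.get("type") == "Int64":
            arr = np.array([int(v) for v in txt], dtype=np.int64)
        else:
            arr = np.array([float(v) for v in txt])
        nc = elem.get("NumberOfComponents")
        if nc:
            arr = arr.reshape(-1, int(nc))
        return arr

    points = parse(piece.find("Points/DataArray"))
    arrays = {e.get("Name"): parse(e) for e in piece.findall("Cells/DataArray")}
    npc = arrays["offsets"][0]
    cells = arrays["connectivity"].reshape(-1, npc)
    point_data = {e.get("Name"): parse(e)
                  for e in piece.findall("PointData/DataArray")}
    cell_data = {e.get("Name"): parse(e)
                 for e in piece.findall("CellData/DataArray")}
    return points, cells, point_data, cell_data


def read_mesh(path):
    """Build a :class:`~atherofem.geometry.Mesh` from a VTU file.

    Integer cell-data arrays become element tags (nonzero entries).  Intended
    for user-supplied quad/hex meshes in the subset of VTU this package
    writes; facet tags are not reconstructed.
    """
    from .geometry import Mesh

    points, cells, _, cell_data = read_vtu(path)
    dim = 2 if cells.shape[1] == 4 else 3
    coords = points[:, :dim]
    tags = {name: np.nonzero(arr)[0]
            for name, arr in cell_data.items() if arr.dtype.kind in "iu"}
    mesh = Mesh(node_coords=coords, elements=cells, element_tags=tags,
                dim=dim, meta={"kind": "imported"})
    mesh.basis()  # validates element orientation
    return mesh


def write_time_series(outdir, result, basename: str = "state") -> list:
    """One VTU per saved step: u, c, phi point data; alpha and max principal
    stress cell data.  Returns the written paths."""
    from . import postproc

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_mesh = result.mesh
    paths = []
    for i, st in enumerate(result.states):
        cd = {"alpha": st.alpha.mean(axis=1)}
        pd_ = {"u": st.u, "c": st.c, "phi": st.phi}
        path = outdir / f"{basename}_{i:04d}.vtu"
        write_vtu(path, sim_mesh.node_coords, sim_mesh.elements,
                  point_data=pd_, cell_data=cd)
        paths.append(path)
    return paths
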