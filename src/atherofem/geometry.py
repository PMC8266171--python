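"""Structured annulus / tube meshes with linear quad and hex elements.

The artery wall is meshed on a polar grid: ``n_r`` element rings through the
wall thickness times ``n_c`` circumferential sectors, optionally extruded
axially into 8-node hexahedra.  Element counts are therefore predictable,
which the tests exploit.

Boundary facets are stored oriented: the node ordering of every tagged facet
is such that its normal (edge rotated by -90 deg in 2D, ``(x1-x0) x (x3-x0)``
in 3D) points out of the solid wall.  The follower pressure load relies on
this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import ElementBasis, element_jacobians, element_measures
from .params import GeometryParams


@dataclass
class Mesh:
    """Unstructured view of a structured wall mesh.

    node_coords : (n_nodes, dim) coordinates in µm
    elements    : (n_elems, 4|8) node indices (quads CCW; VTK hex ordering)
    facet_tags  : name -> (n_facets, 2|4) oriented facet node indices
    element_tags: name -> element index arrays (e.g. ``vv_cut``)
    """

    node_coords: np.ndarray
    elements: np.ndarray
    facet_tags: dict = field(default_factory=dict)
    element_tags: dict = field(default_factory=dict)
    dim: int = 2
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def basis(self) -> ElementBasis:
        return ElementBasis(self.node_coords, self.elements)

    def jacobians(self) -> np.ndarray:
        return element_jacobians(self.node_coords, self.elements)

    def element_measures(self) -> np.ndarray:
        return element_measures(self.node_coords, self.elements)

    def nodes_of_elements(self, elem_ids) -> np.ndarray:
        return np.unique(self.elements[np.asarray(elem_ids, dtype=int)])

    def nodes_of_facets(self, tag: str) -> np.ndarray:
        return np.unique(self.facet_tags[tag])

    def inner_loop(self, plane: int = 0) -> np.ndarray:
        """Ordered (CCW) node ids of the lumen boundary circle.

        For tube meshes ``plane`` selects the axial node plane.
        """
        n_c = self.meta["n_c"]
        loop = np.arange(n_c)
        if self.dim == 3:
            loop = loop + plane * self.meta["nodes_per_plane"]
        return loop


def _annulus_counts(geom: GeometryParams) -> tuple[int, int]:
    n_r = max(3, int(round(geom.wall_thickness / geom.mesh_size)))
    n_c = max(8, int(round(2.0 * np.pi * geom.mid_radius / geom.mesh_size)))
    return n_r, n_c


def make_annulus_mesh(geom: GeometryParams) -> Mesh:
    """Structured 2D annulus of bilinear quads between the lumen and outer wall.

    Node ``i*n_c + j`` sits at radius ``r_in + i*t/n_r`` and azimuth
    ``2*pi*j/n_c``; ring 0 is the lumen surface.
    """
    geom.validate()
    n_r, n_c = _annulus_counts(geom)
    radii = np.linspace(geom.inner_radius, geom.outer_radius, n_r + 1)
    thetas = 2.0 * np.pi * np.arange(n_c) / n_c
    rr, tt = np.meshgrid(radii, thetas, indexing="ij")
    coords = np.column_stack([(rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel()])

    i = np.repeat(np.arange(n_r), n_c)
    j = np.tile(np.arange(n_c), n_r)
    jp = (j + 1) % n_c
    elements = np.column_stack([i * n_c + j, (i + 1) * n_c + j, (i + 1) * n_c + jp, i * n_c + jp])

    jj = np.arange(n_c)
    jjp = (jj + 1) % n_c
    inner = np.column_stack([jj, jjp])                       # CCW: -90 deg normal -> axis
    outer_base = n_r * n_c
    outer = np.column_stack([outer_base + jjp, outer_base + jj])  # CW: normal away from axis

    mesh = Mesh(
        node_coords=coords,
        elements=elements.astype(np.int64),
        facet_tags={"inner_surface": inner.astype(np.int64), "outer_surface": outer.astype(np.int64)},
        dim=2,
        meta={
            "kind": "annulus",
            "n_r": n_r,
            "n_c": n_c,
            "r_in": geom.inner_radius,
            "r_out": geom.outer_radius,
            "h": geom.mesh_size,
        },
    )
    mesh.basis()  # raises on inverted elements
    return mesh


def make_tube_mesh(geom: GeometryParams) -> Mesh:
    """Axial extrusion of the annulus into 8-node hexahedra.

    Node ids repeat the annulus numbering plane by plane along +z; the axial
    end facets are tagged ``axial_end_minus`` (z=0) and ``axial_end_plus``.
    """
    geom.validate()
    annulus = make_annulus_mesh(geom)
    n_z = max(1, int(round(geom.length / geom.mesh_size)))
    n_r, n_c = annulus.meta["n_r"], annulus.meta["n_c"]
    npp = annulus.n_nodes
    zs = np.linspace(0.0, geom.length, n_z + 1)

    coords = np.empty((npp * (n_z + 1), 3))
    for k, z in enumerate(zs):
        coords[k * npp:(k + 1) * npp, :2] = annulus.node_coords
        coords[k * npp:(k + 1) * npp, 2] = z

    quads = annulus.elements
    elements = np.empty((annulus.n_elements * n_z, 8), dtype=np.int64)
    for k in range(n_z):
        elements[k * annulus.n_elements:(k + 1) * annulus.n_elements, :4] = quads + k * npp
        elements[k * annulus.n_elements:(k + 1) * annulus.n_elements, 4:] = quads + (k + 1) * npp

    jj = np.arange(n_c)
    jjp = (jj + 1) % n_c
    inner_facets = []
    outer_facets = []
    outer_base = n_r * n_c
    for k in range(n_z):
        lo, hi = k * npp, (k + 1) * npp
        # inner: normal toward the axis
        inner_facets.append(np.column_stack([jj + lo, jj + hi, jjp + hi, jjp + lo]))
        # outer: normal away from the axis
        outer_facets.append(np.column_stack(
            [outer_base + jj + lo, outer_base + jjp + lo, outer_base + jjp + hi, outer_base + jj + hi]))
    end_minus = quads[:, ::-1].copy()                    # reversed -> normal -z
    end_plus = quads + n_z * npp                         # CCW in plane -> normal +z

    mesh = Mesh(
        node_coords=coords,
        elements=elements,
        facet_tags={
            "inner_surface": np.vstack(inner_facets).astype(np.int64),
            "outer_surface": np.vstack(outer_facets).astype(np.int64),
            "axial_end_minus": end_minus.astype(np.int64),
            "axial_end_plus": end_plus.astype(np.int64),
        },
        dim=3,
        meta={
            "kind": "tube",
            "n_r": n_r,
            "n_c": n_c,
            "n_z": n_z,
            "nodes_per_plane": npp,
            "elems_per_layer": annulus.n_elements,
            "r_in": geom.inner_radius,
            "r_out": geom.outer_radius,
            "length": geom.length,
            "h": geom.mesh_size,
        },
    )
    mesh.basis()
    return mesh


def make_strip_mesh(length: float, width: float, hx: float, hy: float | None = None) -> Mesh:
    """Rectangular strip [0,L]x[0,W] of quads; used for 1D-reduction studies."""
    hy = hx if hy is None else hy
    n_x = max(1, int(round(length / hx)))
    n_y = max(1, int(round(width / hy)))
    xs = np.linspace(0.0, length, n_x + 1)
    ys = np.linspace(0.0, width, n_y + 1)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    nid = lambda i, j: i * (n_y + 1) + j
    elems = []
    for i in range(n_x):
        for j in range(n_y):
            elems.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
    left = np.array([[nid(0, j + 1), nid(0, j)] for j in range(n_y)])
    right = np.array([[nid(n_x, j), nid(n_x, j + 1)] for j in range(n_y)])
    mesh = Mesh(
        node_coords=coords,
        elements=np.asarray(elems, dtype=np.int64),
        facet_tags={"left": left.astype(np.int64), "right": right.astype(np.int64)},
        dim=2,
        meta={"kind": "strip", "n_x": n_x, "n_y": n_y, "length": length, "width": width},
    )
    mesh.basis()
    return mesh


def azimuth_of_point(x: np.ndarray, axis_tol: float = 1.0e-9) -> np.ndarray:
    """Azimuth angle in [0, 2π) of point(s) about the artery axis (z).

    Raises ``ValueError`` for points on the axis, where the angle is undefined.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    r = np.hypot(pts[:, 0], pts[:, 1])
    if np.any(r < axis_tol):
        raise ValueError("azimuth undefined on the artery axis")
    th = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2.0 * np.pi)
    return float(th[0]) if single else th


def radius_of_point(x: np.ndarray) -> np.ndarray:
    """Distance from the artery axis (z)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    r = np.hypot(x[:, 0], x[:, 1])
    return float(r[0]) if r.shape[0] == 1 and np.asarray(x).ndim == 1 else r


_QUAD_FACES = [(0, 1), (1, 2), (2, 3), (3, 0)]
_HEX_FACES = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4), (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7)]


def facet_multiplicity(mesh: Mesh) -> dict:
    """Map sorted facet node-tuple -> number of elements sharing it.

    Interior facets of a watertight mesh appear exactly twice, boundary facets
    exactly once.
    """
    faces = _QUAD_FACES if mesh.dim == 2 else _HEX_FACES
    counts: dict = {}
    for elem in mesh.elements:
        for f in faces:
            key = tuple(sorted(elem[list(f)]))
            counts[key] = counts.get(key, 0) + 1
    return counts
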