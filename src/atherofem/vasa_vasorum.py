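"""Stochastic tree-fractal vasa-vasorum networks.

The outer artery wall is nourished by microvessels entering from the
adventitial surface.  They are modelled geometrically as recursive
tree fractals: a trunk of length ``L0`` pointing inward, then per level
``k = 2..4`` children scaled by ``lambda_k`` — two children spread by the
full opening angle ``gamma_k`` in 2D, one child per (azimuth, elevation)
pair in 3D.  Lengths and angles carry multiplicative Gaussian jitter.
Trees are clipped to the outer half of the wall (they penetrate at most to
mid-wall).  Mesh elements cut by any segment are tagged ``vv_cut`` and later
receive the maximum-nutrient Dirichlet condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Mesh, azimuth_of_point
from .params import FractalParams, GeometryParams

_TOL = 1.0e-9


@dataclass
class FractalTree:
    """Polyline segments (start, end, level) of one vasa-vasorum tree."""

    starts: np.ndarray       # (n_seg, dim)
    ends: np.ndarray         # (n_seg, dim)
    levels: np.ndarray       # (n_seg,)
    anchor: np.ndarray       # root point on the outer surface
    dim: int = 2
    meta: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return self.starts.shape[0]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.ends - self.starts, axis=1)

    def all_points(self) -> np.ndarray:
        return np.vstack([self.starts, self.ends])


def _clip_segment_to_band(p: np.ndarray, q: np.ndarray,
                          r_min: float | None, r_max: float | None):
    """Clip segment p->q to the annular band r_min <= |x_xy| <= r_max.

    Returns a list of (sub_p, sub_q) pieces (0, 1 or 2 pieces).
    """
    v = q - p
    a = float(v[0] ** 2 + v[1] ** 2)
    b = 2.0 * float(p[0] * v[0] + p[1] * v[1])
    c0 = float(p[0] ** 2 + p[1] ** 2)

    def rho2(t):
        return a * t * t + b * t + c0

    # intervals of t in [0,1] satisfying both constraints
    intervals = [(0.0, 1.0)]

    def intersect_leq(r, intervals):
        # rho2(t) <= r^2 : convex quadratic -> single interval
        out = []
        if a < _TOL:
            keep = c0 <= r * r + _TOL
            return intervals if keep else []
        disc = b * b - 4.0 * a * (c0 - r * r)
        if disc < 0.0:
            return []
        sq = np.sqrt(disc)
        t1, t2 = (-b - sq) / (2 * a), (-b + sq) / (2 * a)
        for lo, hi in intervals:
            nlo, nhi = max(lo, t1), min(hi, t2)
            if nhi > nlo + _TOL:
                out.append((nlo, nhi))
        return out

    def intersect_geq(r, intervals):
        # rho2(t) >= r^2 : complement of an interval
        out = []
        if a < _TOL:
            keep = c0 >= r * r - _TOL
            return intervals if keep else []
        disc = b * b - 4.0 * a * (c0 - r * r)
        if disc < 0.0:
            return intervals
        sq = np.sqrt(disc)
        t1, t2 = (-b - sq) / (2 * a), (-b + sq) / (2 * a)
        for lo, hi in intervals:
            if t1 > lo + _TOL:
                out.append((lo, min(hi, t1)))
            if t2 < hi - _TOL:
                out.append((max(lo, t2), hi))
        return [(lo, hi) for lo, hi in out if hi > lo + _TOL]

    if r_max is not None:
        intervals = intersect_leq(r_max, intervals)
    if r_min is not None:
        intervals = intersect_geq(r_min, intervals)
    return [(p + lo * v, p + hi * v) for lo, hi in intervals]


def _jitter(rng: np.random.Generator, jitter: float) -> float:
    return 1.0 + jitter * rng.standard_normal() if jitter > 0 else 1.0


def _grow(params: FractalParams, rng, start, direction, length, level,
          segments, r_clip_min, r_clip_max, dim):
    """Recursive helper: emit the segment from ``start`` and recurse."""
    end = start + length * direction
    pieces = _clip_segment_to_band(start, end, r_clip_min, r_clip_max)
    for sp, sq in pieces:
        segments.append((sp, sq, level))
    n_levels = 1 + len(params.length_ratios)
    if level >= n_levels:
        return
    # recurse only when the branch point itself stayed inside the band
    r_end = float(np.hypot(end[0], end[1]))
    if r_clip_min is not None and r_end < r_clip_min - _TOL:
        return
    if r_clip_max is not None and r_end > r_clip_max + _TOL:
        return
    lam = params.length_ratios[level - 1]
    if dim == 2:
        gamma = params.branch_angles[level - 1]
        for sign in (+1.0, -1.0):
            ang = sign * 0.5 * gamma * _jitter(rng, params.jitter)
            ca, sa = np.cos(ang), np.sin(ang)
            child_dir = np.array([ca * direction[0] - sa * direction[1],
                                  sa * direction[0] + ca * direction[1]])
            child_len = lam * length * _jitter(rng, params.jitter)
            _grow(params, rng, end, child_dir, child_len, level + 1,
                  segments, r_clip_min, r_clip_max, dim)
    else:
        # orthonormal frame around the parent direction
        d = direction / np.linalg.norm(direction)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(d @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(d, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        for g_az, g_el in zip(params.azimuth_angles, params.elevation_angles):
            el = g_el * _jitter(rng, params.jitter)
            az = g_az * _jitter(rng, params.jitter)
            child_dir = (np.sin(el) * d
                         + np.cos(el) * (np.cos(az) * e1 + np.sin(az) * e2))
            child_len = lam * length * _jitter(rng, params.jitter)
            _grow(params, rng, end, child_dir, child_len, level + 1,
                  segments, r_clip_min, r_clip_max, dim)


def _generate_tree(params, anchor, inward_direction, dim, rng=None,
                   r_clip_min=None, r_clip_max=None) -> FractalTree:
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    anchor = np.asarray(anchor, dtype=float)
    d = np.asarray(inward_direction, dtype=float)
    d = d / np.linalg.norm(d)
    segments: list = []
    trunk_len = params.trunk_length * _jitter(rng, params.jitter)
    _grow(params, rng, anchor, d, trunk_len, 1, segments,
          r_clip_min, r_clip_max, dim)
    if segments:
        starts = np.array([s for s, _, _ in segments])
        ends = np.array([e for _, e, _ in segments])
        levels = np.array([l for _, _, l in segments], dtype=int)
    else:  # fully clipped tree
        starts = np.zeros((0, dim))
        ends = np.zeros((0, dim))
        levels = np.zeros(0, dtype=int)
    return FractalTree(starts=starts, ends=ends, levels=levels,
                       anchor=anchor, dim=dim)


def generate_tree_2d(params: FractalParams, anchor, inward_direction,
                     rng=None, r_clip_min=None, r_clip_max=None) -> FractalTree:
    """One planar tree: trunk along ``inward_direction``, binary branching
    spread symmetrically by ±gamma_k/2 per level."""
    return _generate_tree(params, anchor, inward_direction, 2, rng,
                          r_clip_min, r_clip_max)


def generate_tree_3d(params: FractalParams, anchor, inward_direction,
                     rng=None, r_clip_min=None, r_clip_max=None) -> FractalTree:
    """One 3D tree: each branch node spawns one child per
    (azimuth, elevation) pair, rotated into the parent's local frame."""
    return _generate_tree(params, anchor, inward_direction, 3, rng,
                          r_clip_min, r_clip_max)


def generate_forest(params: FractalParams, geom: GeometryParams, dim: int,
                    ) -> list[FractalTree]:
    """``n_trees`` trees anchored equally spaced on the outer surface.

    Anchors sit at azimuths ``2*pi*i/n_trees``; in 3D they are staggered
    axially at ``z_i = (i + 1/2) L / n_trees``.  Trees are clipped to the
    outer half of the wall (mid-wall penetration limit).
    """
    r_out = geom.outer_radius
    r_mid = geom.mid_radius
    rng = np.random.default_rng(params.seed)
    trees = []
    for i in range(params.n_trees):
        th = 2.0 * np.pi * i / params.n_trees
        if dim == 2:
            anchor = r_out * np.array([np.cos(th), np.sin(th)])
            inward = -np.array([np.cos(th), np.sin(th)])
            tree = generate_tree_2d(params, anchor, inward, rng=rng,
                                    r_clip_min=r_mid, r_clip_max=r_out)
        else:
            z = (i + 0.5) * geom.length / params.n_trees
            anchor = np.array([r_out * np.cos(th), r_out * np.sin(th), z])
            inward = -np.array([np.cos(th), np.sin(th), 0.0])
            tree = generate_tree_3d(params, anchor, inward, rng=rng,
                                    r_clip_min=r_mid, r_clip_max=r_out)
        tree.meta["anchor_azimuth"] = th
        trees.append(tree)
    return trees


# ---------------------------------------------------------------------------
# segment / element intersection tagging
# ---------------------------------------------------------------------------

def _tag_2d(mesh: Mesh, trees) -> list[np.ndarray]:
    from shapely import STRtree
    from shapely.geometry import LineString, Polygon

    polys = [Polygon(mesh.node_coords[e]) for e in mesh.elements]
    tree_index = STRtree(polys)
    per_tree = []
    for t in trees:
        hit = set()
        for p, q in zip(t.starts, t.ends):
            seg = LineString([p, q])
            for idx in tree_index.query(seg):
                if polys[idx].intersects(seg):
                    hit.add(int(idx))
        per_tree.append(np.array(sorted(hit), dtype=int))
    return per_tree


def _hex_planes(coords: np.ndarray):
    """Outward (point, normal) pairs of the 6 planar faces of one hex."""
    faces = [(0, 1, 2, 3), (4, 5, 6, 7), (0, 1, 5, 4),
             (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7)]
    centroid = coords.mean(axis=0)
    planes = []
    for f in faces:
        pts = coords[list(f)]
        n = np.cross(pts[1] - pts[0], pts[3] - pts[0])
        nn = np.linalg.norm(n)
        if nn < _TOL:
            continue
        n = n / nn
        x0 = pts.mean(axis=0)
        if (centroid - x0) @ n > 0:
            n = -n
        planes.append((x0, n))
    return planes


def _segment_hits_hex(p, q, planes, tol=1.0e-9) -> bool:
    """Cyrus-Beck clip of segment p->q against the hex half-spaces."""
    t_lo, t_hi = 0.0, 1.0
    v = q - p
    for x0, n in planes:
        denom = v @ n
        num = (x0 - p) @ n + tol
        if abs(denom) < _TOL:
            if (p - x0) @ n > tol:
                return False
            continue
        t = num / denom
        if denom > 0:
            t_hi = min(t_hi, t)
        else:
            t_lo = max(t_lo, t)
        if t_lo > t_hi:
            return False
    return True


def _tag_3d(mesh: Mesh, trees) -> list[np.ndarray]:
    coords = mesh.node_coords[mesh.elements]            # (E, 8, 3)
    lo = coords.min(axis=1) - _TOL
    hi = coords.max(axis=1) + _TOL
    planes = [_hex_planes(c) for c in coords]
    per_tree = []
    for t in trees:
        hit = set()
        for p, q in zip(t.starts, t.ends):
            slo = np.minimum(p, q)
            shi = np.maximum(p, q)
            cand = np.nonzero(np.all(hi >= slo, axis=1) & np.all(lo <= shi, axis=1))[0]
            for e in cand:
                if _segment_hits_hex(p, q, planes[e]):
                    hit.add(int(e))
        per_tree.append(np.array(sorted(hit), dtype=int))
    return per_tree


def tag_cut_elements(mesh: Mesh, trees, store: bool = True) -> np.ndarray:
    """Elements whose closed hull intersects any tree segment (inclusive).

    The union over trees is stored as the ``vv_cut`` element tag; ties
    (segment on a shared facet) tag all touching elements.
    """
    per_tree = tag_cut_elements_per_tree(mesh, trees)
    union = (np.unique(np.concatenate(per_tree)) if per_tree
             else np.zeros(0, dtype=int))
    if store:
        mesh.element_tags["vv_cut"] = union
    return union


def tag_cut_elements_per_tree(mesh: Mesh, trees) -> list[np.ndarray]:
    """Per-tree cut-element sets (needed for occluding a single tree)."""
    trees = list(trees)
    if mesh.dim == 2:
        return _tag_2d(mesh, trees)
    return _tag_3d(mesh, trees)


def occluded_tree_index(trees, geom: GeometryParams) -> int:
    """Index of the tree whose anchor is nearest the occlusion arc coordinate.

    The arc ``S`` is measured counter-clockwise along the mid-wall circle
    from the positive x-axis.
    """
    theta_occ = geom.occlusion_arc / geom.mid_radius
    best, best_d = 0, np.inf
    for i, t in enumerate(trees):
        th = t.meta.get("anchor_azimuth")
        if th is None:
            th = azimuth_of_point(t.anchor)
        d = abs((th - theta_occ + np.pi) % (2.0 * np.pi) - np.pi)
        if d < best_d:
            best, best_d = i, d
    return best
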