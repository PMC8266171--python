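"""Programmatic test inputs: analytic oracles, 1D reductions, canned cases.

The oracles here are deliberately independent of the production code paths
(closed forms and brute-force geometry instead of the FEM kernel) so that
tests can cross-check the solver against them.

The canned 2D disease scenarios mirror the three study configurations
(no fibers / fibers / fibers + vasa vasorum) at a coarsened *test*
resolution: mesh size 1 µm instead of 0.5 µm, with the phase-field interface
parameters rescaled for that mesh (see ``TEST_RESOLUTION`` below and the
methods note).  The ``*_paper`` variants keep the nominal fine-resolution
parameter set and are provided for completeness; they are far too expensive
for routine testing.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .geometry import make_strip_mesh
from .params import GeometryParams, SimulationConfig

# ---------------------------------------------------------------------------
# closed-form oracles
# ---------------------------------------------------------------------------

def slab_nutrient_profile(x, length, D, R_c, c_max):
    """Steady 1D diffusion-consumption: ``D c'' = R_c`` on [0, L],
    ``c(0) = c_max``, zero flux at L: ``c = c_max - (R_c/2D)(2 L x - x^2)``."""
    x = np.asarray(x, dtype=float)
    return c_max - (R_c / (2.0 * D)) * (2.0 * length * x - x ** 2)


def radial_nutrient_profile(r, r_in, r_out, D, R_c, c_max):
    """Steady radial diffusion-consumption on an annulus:
    ``D (c'' + c'/r) = R_c``, ``c(r_in) = c_max``, zero flux at ``r_out``."""
    r = np.asarray(r, dtype=float)
    return c_max + (R_c / D) * ((r ** 2 - r_in ** 2) / 4.0
                                - 0.5 * r_out ** 2 * np.log(r / r_in))


def lame_annulus_displacement(r, r_in, r_out, p, mu, nu):
    """Plane-strain thick-wall cylinder under internal pressure (linear
    elasticity, shear modulus mu, Poisson nu): radial displacement u(r)."""
    r = np.asarray(r, dtype=float)
    E = 2.0 * mu * (1.0 + nu)
    A = (1.0 + nu) * p * r_in ** 2 / (E * (r_out ** 2 - r_in ** 2))
    return A * ((1.0 - 2.0 * nu) * r + r_out ** 2 / r)


def fan_triangulation_area(points: np.ndarray) -> float:
    """Polygon area by fan triangulation from the centroid (star-shaped
    polygons); independent of the shoelace route."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    area = 0.0
    n = len(pts)
    for i in range(n):
        a = pts[i] - c
        b = pts[(i + 1) % n] - c
        area += 0.5 * (a[0] * b[1] - a[1] * b[0])
    return area


def segment_intersects_quad_bruteforce(p, q, quad: np.ndarray, tol=1.0e-12) -> bool:
    """Inclusive segment/convex-quad intersection by elementary predicates:
    endpoint containment or edge-pair intersection (no shapely, no clipping)."""

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def inside(pt):
        signs = [cross(quad[i], quad[(i + 1) % 4], pt) for i in range(4)]
        return all(s >= -tol for s in signs) or all(s <= tol for s in signs)

    if inside(p) or inside(q):
        return True

    def seg_seg(a, b, c, d):
        d1, d2 = cross(c, d, a), cross(c, d, b)
        d3, d4 = cross(a, b, c), cross(a, b, d)
        if ((d1 > tol and d2 < -tol) or (d1 < -tol and d2 > tol)) and \
           ((d3 > tol and d4 < -tol) or (d3 < -tol and d4 > tol)):
            return True

        def on(a, b, c):
            return (abs(cross(a, b, c)) <= tol
                    and min(a[0], b[0]) - tol <= c[0] <= max(a[0], b[0]) + tol
                    and min(a[1], b[1]) - tol <= c[1] <= max(a[1], b[1]) + tol)

        return on(c, d, a) or on(c, d, b) or on(a, b, c) or on(a, b, d)

    return any(seg_seg(p, q, quad[i], quad[(i + 1) % 4]) for i in range(4))


# ---------------------------------------------------------------------------
# manufactured cases
# ---------------------------------------------------------------------------

def manufactured_diffusion_case(h: float = 2.5, phi_uniform: float = 0.0,
                                consumption: float | None = None):
    """Annulus reaction-diffusion fixture: configuration plus its radial
    closed form (inner Dirichlet ``c_max``, outer zero flux, frozen phase)."""
    cfg = SimulationConfig(
        dim=2,
        geometry=GeometryParams(mesh_size=h),
        fix_displacement=True,
        fix_phase=True,
        seed_lesion=False,
        label=f"diffusion_h{h}",
    )
    cfg.solver = replace(cfg.solver, p_max=0.0, dt=1.0, t_end=1.0)
    if consumption is not None:
        cfg.nutrient = replace(cfg.nutrient, consumption=consumption)
    n = cfg.nutrient
    from .nutrient import diffusivity
    D = float(diffusivity(phi_uniform, n))

    def analytic(r):
        return radial_nutrient_profile(r, cfg.geometry.inner_radius,
                                       cfg.geometry.outer_radius,
                                       D, n.consumption, n.c_max)

    return cfg, analytic


def interface_speed_case(r_s: float = 0.1, h: float = 0.02,
                         length: float = 4.0, t_end: float = 6.0,
                         front_x: float = 1.0):
    """1D strip fixture for the front-advection calibration.

    A fixed linear nutrient profile below the scarcity threshold drives the
    seeded half-domain interface toward +x with speed ``R_s``; mechanics is
    clamped and the nutrient frozen.  Returns (config, mesh, phi0, c0).
    """
    mesh = make_strip_mesh(length, h, h)
    mesh.meta["h"] = h
    cfg = SimulationConfig(
        dim=2,
        fix_displacement=True,
        freeze_nutrient=True,
        seed_lesion=False,
        label=f"front_speed_Rs{r_s}",
    )
    cfg.phasefield = replace(cfg.phasefield, source_rate=r_s)
    cfg.solver = replace(cfg.solver, p_max=0.0, dt=min(0.05, 0.5 * h / max(r_s, 1e-12)),
                         t_end=t_end, save_every=5)
    pf = cfg.phasefield
    k_prof = 2.0 * math.sqrt(2.0) * pf.barrier / pf.interface
    x = mesh.node_coords[:, 0]
    phi0 = 0.5 * (1.0 - np.tanh(k_prof * (x - front_x)))
    c0 = 0.5 - 0.05 * x          # decreasing toward +x, everywhere below c_cri
    return cfg, mesh, phi0, c0


def front_position(mesh, phi, level: float = 0.5) -> float:
    """x-coordinate of the phi = level crossing on the strip's bottom edge."""
    n_y = mesh.meta["n_y"]
    ids = np.arange(mesh.meta["n_x"] + 1) * (n_y + 1)
    x = mesh.node_coords[ids, 0]
    p = phi[ids]
    above = p >= level
    if not above.any():
        return float(x[0])
    i = int(np.max(np.nonzero(above)[0]))
    if i == len(x) - 1:
        return float(x[-1])
    # linear interpolation of the downward crossing
    t = (p[i] - level) / (p[i] - p[i + 1])
    return float(x[i] + t * (x[i + 1] - x[i]))


def measure_front_speed(r_s: float, t_window=(2.0, 6.0), **kwargs):
    """Run the strip fixture and fit the front trajectory's slope."""
    from .fem_solver import Simulation

    cfg, mesh, phi0, c0 = interface_speed_case(r_s=r_s, t_end=t_window[1], **kwargs)
    sim = Simulation(cfg, mesh=mesh)
    res = sim.run(phi0=phi0, c0=c0)
    ts, xs = [], []
    for st in res.states:
        if st.time >= t_window[0]:
            ts.append(st.time)
            xs.append(front_position(mesh, st.phi))
    slope = np.polyfit(ts, xs, 1)[0]
    return float(slope), res


# ---------------------------------------------------------------------------
# canned disease scenarios
# ---------------------------------------------------------------------------

#: coarsened study resolution used by the shipped scenario runs: 1 µm mesh,
#: interface parameters rescaled so the diffuse front spans ~4 elements and
#: curvature-driven shrinkage stays well below the advection speed R_s.
TEST_RESOLUTION = {
    "mesh_size": 1.0,
    "interface": 0.2,
    "barrier": 0.07,
    "dt": 0.25,
    "t_end": 10.0,
    "seed_radius": 3.0,
}

CANNED_CASES = ("no_fiber_no_vv", "fiber_no_vv", "fiber_vv", "tube3d_coarse")


def canned_case(name: str, paper_resolution: bool = False) -> SimulationConfig:
    """Ready-to-run configuration for one of the canonical scenarios.

    ``no_fiber_no_vv``: isotropic wall (eta = 0), lumen nourishment only.
    ``fiber_no_vv``: circumferential in-plane fibers (theta_el = 0).
    ``fiber_vv``: fibers plus an 8-tree vasa-vasorum network with the tree
    nearest the occlusion arc removed from the nourishment set.
    ``tube3d_coarse``: short coarse 3D tube with fibers and VV.
    """
    if name not in CANNED_CASES:
        raise ValueError(f"unknown canned case {name!r}; choose from {CANNED_CASES}")

    cfg = SimulationConfig(label=name)
    if not paper_resolution:
        tr = TEST_RESOLUTION
        cfg.geometry = replace(cfg.geometry, mesh_size=tr["mesh_size"])
        cfg.phasefield = replace(cfg.phasefield, interface=tr["interface"],
                                 barrier=tr["barrier"])
        cfg.solver = replace(cfg.solver, dt=tr["dt"], t_end=tr["t_end"],
                             save_every=4)
        cfg.seed_radius = tr["seed_radius"]

    if name == "no_fiber_no_vv":
        cfg.material = replace(cfg.material, fiber_stiffness=0.0)
    elif name == "fiber_no_vv":
        cfg.material = replace(cfg.material, fiber_elevation=0.0)
    elif name == "fiber_vv":
        cfg.material = replace(cfg.material, fiber_elevation=0.0)
        cfg.enable_vv = True
    elif name == "tube3d_coarse":
        cfg.dim = 3
        cfg.material = replace(cfg.material, fiber_elevation=math.radians(60.0))
        cfg.enable_vv = True
        cfg.vasa_vasorum = replace(cfg.vasa_vasorum, n_trees=4)
        if not paper_resolution:
            # the 4 µm hex mesh needs a wider diffuse interface to resolve
            cfg.geometry = replace(cfg.geometry, mesh_size=4.0, length=24.0)
            cfg.phasefield = replace(cfg.phasefield, interface=0.4, barrier=0.057)
            cfg.seed_radius = 5.0
            # absolute residual tolerance rescaled for the ~64x larger
            # element volumes of the 4 µm hex mesh
            cfg.solver = replace(cfg.solver, dt=0.5, t_end=1.0, save_every=1,
                                 newton_tol=2.0e-6)
    cfg.validate()
    return cfg
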