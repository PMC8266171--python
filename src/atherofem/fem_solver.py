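"""Monolithic three-field FEM solver with Newton-Raphson and pseudo-time stepping.

Unknowns per node are ``[u (dim), c, phi]`` (4 DOFs in 2D, 5 in 3D, node-major
ordering).  Each pseudo-time step freezes the lagged quantities (growth
variable ``alpha``, the advection direction ``grad c / |grad c|`` and the
scarcity gate of the inflammation source), solves the coupled residual of the
mechanical equilibrium, steady nutrient transport and backward-Euler
Allen-Cahn equations monolithically, then updates ``alpha`` at the Gauss
points from the converged inflammation field.

Mechanics is assembled in total-Lagrangian form on the reference
configuration (``F = I + Grad u``, equivalent to the spatial-gradient
definition ``F = (I - grad u)^{-1}``); the lumen pressure is a follower load
on the deformed inner surface with its geometric linearization included.
The transport and phase-field integrals are evaluated on the reference
configuration as well.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import inflammation as infl
from . import mechanics as mech
from . import nutrient as nutr
from .geometry import Mesh, azimuth_of_point, make_annulus_mesh, make_tube_mesh
from .params import SimulationConfig
from .vasa_vasorum import (generate_forest, occluded_tree_index,
                           tag_cut_elements_per_tree)

_EPS3 = np.zeros((3, 3, 3))
_EPS3[0, 1, 2] = _EPS3[1, 2, 0] = _EPS3[2, 0, 1] = 1.0
_EPS3[0, 2, 1] = _EPS3[2, 1, 0] = _EPS3[1, 0, 2] = -1.0


class SolverError(RuntimeError):
    """Newton divergence that persisted through all step halvings."""


class _StepFailure(RuntimeError):
    """Recoverable failure of one Newton attempt (divergence / inverted element)."""


@dataclass
class FieldState:
    """Nodal fields and Gauss-point internal variables at one pseudo-time."""

    u: np.ndarray          # (n_nodes, dim)
    c: np.ndarray          # (n_nodes,)
    phi: np.ndarray        # (n_nodes,)
    alpha: np.ndarray      # (n_elems, ngp)
    time: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.u.copy(), self.c.copy(), self.phi.copy(),
                          self.alpha.copy(), self.time)


@dataclass
class SimulationResult:
    """Saved states plus derived scalar series of one run."""

    mesh: Mesh
    config: SimulationConfig
    states: list = field(default_factory=list)
    series: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)
    trees: list = field(default_factory=list)

    def series_frame(self):
        import pandas as pd
        return pd.DataFrame(self.series)


class Simulation:
    """Assembles and advances the coupled artery model for one configuration."""

    def __init__(self, config: SimulationConfig, mesh: Mesh | None = None):
        config.validate()
        self.config = config
        geom = config.geometry
        if mesh is None:
            mesh = make_annulus_mesh(geom) if config.dim == 2 else make_tube_mesh(geom)
        self.mesh = mesh
        self.dim = mesh.dim
        self.basis = mesh.basis()
        self.n_nodes = mesh.n_nodes
        self.ndpn = self.dim + 2
        self.n_dof = self.n_nodes * self.ndpn
        self.warnings: list[str] = []

        # fiber directions at reference Gauss points
        gp = self.basis.gp_coords
        mat = config.material
        if mat.fiber_stiffness > 0.0:
            th_az = np.arctan2(gp[..., 1], gp[..., 0])
            self.fiber_gp = mech.fiber_direction(th_az, mat.fiber_elevation)
        else:
            self.fiber_gp = np.broadcast_to(np.array([0.0, 1.0, 0.0]),
                                            gp.shape[:2] + (3,))

        # vasa vasorum
        self.trees: list = []
        self.vv_nodes = np.zeros(0, dtype=int)
        if config.enable_vv:
            self.trees = generate_forest(config.vasa_vasorum, geom, self.dim)
            per_tree = tag_cut_elements_per_tree(mesh, self.trees)
            union = (np.unique(np.concatenate(per_tree)) if per_tree
                     else np.zeros(0, dtype=int))
            mesh.element_tags["vv_cut"] = union
            active = list(range(len(self.trees)))
            if config.occlude_tree and self.trees:
                occ = occluded_tree_index(self.trees, geom)
                active = [i for i in active if i != occ]
                self.occluded_tree = occ
            else:
                self.occluded_tree = None
            nourished = ([per_tree[i] for i in active] or [np.zeros(0, dtype=int)])
            elems = np.unique(np.concatenate(nourished))
            if elems.size:
                self.vv_nodes = mesh.nodes_of_elements(elems)

        self._build_dof_maps()
        self._build_pressure_facets()
        self.dirichlet_tags = (list(config.dirichlet_c_tags)
                               if config.dirichlet_c_tags else None)

    # ------------------------------------------------------------------
    # DOF bookkeeping
    # ------------------------------------------------------------------
    def _build_dof_maps(self):
        elems = self.mesh.elements
        nn = elems.shape[1]
        dim, ndpn = self.dim, self.ndpn
        base = elems * ndpn                                  # (E, nn)
        self.edof_u = (base[:, :, None] + np.arange(dim)).reshape(elems.shape[0], nn * dim)
        self.edof_c = base + dim
        self.edof_phi = base + dim + 1

        def pair(rows, cols):
            # row-major flattening of per-element dense blocks K[a, b]
            r = np.broadcast_to(rows[:, :, None],
                                rows.shape + (cols.shape[1],))
            c = np.broadcast_to(cols[:, None, :],
                                (cols.shape[0], rows.shape[1], cols.shape[1]))
            return r.ravel(), c.ravel()

        self.idx_uu = pair(self.edof_u, self.edof_u)
        self.idx_cc = pair(self.edof_c, self.edof_c)
        self.idx_cphi = pair(self.edof_c, self.edof_phi)
        self.idx_phiphi = pair(self.edof_phi, self.edof_phi)

    def _build_pressure_facets(self):
        """Precompute follower-load data for the lumen surface."""
        self.press_facets = None
        tags = self.mesh.facet_tags
        if "inner_surface" not in tags:
            return
        facets = tags["inner_surface"]
        self.press_facets = facets
        dim, ndpn = self.dim, self.ndpn
        fdof = (facets * ndpn)[:, :, None] + np.arange(dim)   # (F, nf, dim)
        self.press_dofs = fdof.reshape(facets.shape[0], -1)
        rows = self.press_dofs[:, :, None] * np.ones(
            (1, 1, self.press_dofs.shape[1]), dtype=int)
        cols = self.press_dofs[:, None, :] * np.ones(
            (1, self.press_dofs.shape[1], 1), dtype=int)
        self.idx_press = (rows.ravel(), cols.ravel())
        if dim == 3:
            from .fem import gauss_points, shape_functions
            xi, w = gauss_points(2)
            N, dN = shape_functions(2, xi)
            self._facet_N, self._facet_dN, self._facet_w = N, dN, w

    # ------------------------------------------------------------------
    # boundary conditions
    # ------------------------------------------------------------------
    def _nearest_node(self, target_angle: float, ring: str = "outer",
                      plane: int = 0) -> int:
        mesh = self.mesh
        n_c = mesh.meta["n_c"]
        n_r = mesh.meta["n_r"]
        base = n_r * n_c if ring == "outer" else 0
        ids = base + np.arange(n_c)
        if self.dim == 3:
            ids = ids + plane * mesh.meta["nodes_per_plane"]
        th = azimuth_of_point(mesh.node_coords[ids])
        d = np.abs((th - target_angle + np.pi) % (2 * np.pi) - np.pi)
        return int(ids[np.argmin(d)])

    def dirichlet_dofs(self, state_init: FieldState):
        """Resolve the constrained DOF set: (indices, prescribed values).

        Lumen surface: ``c = c_max``; VV-cut element nodes (minus the occluded
        tree): ``c = c_max``; rigid-body modes of ``u`` removed by minimal
        point constraints (axial ends stay free in 3D); ``phi`` has natural
        boundaries only.  The ``fix_*``/``freeze_*`` config flags clamp whole
        fields at their initial values for reduced studies.
        """
        cfg = self.config
        dim, ndpn = self.dim, self.ndpn
        idx, val = [], []

        def add(node, comp, value):
            idx.append(node * ndpn + comp)
            val.append(value)

        c_comp, phi_comp = dim, dim + 1
        mesh = self.mesh

        if cfg.freeze_nutrient:
            for n in range(self.n_nodes):
                add(n, c_comp, state_init.c[n])
        else:
            tags = self.dirichlet_tags or (
                ["inner_surface"] if "inner_surface" in mesh.facet_tags else [])
            seen = set()
            for tag in tags:
                for n in mesh.nodes_of_facets(tag):
                    if n not in seen:
                        seen.add(int(n))
                        add(int(n), c_comp, cfg.nutrient.c_max)
            for n in self.vv_nodes:
                if int(n) not in seen:
                    seen.add(int(n))
                    add(int(n), c_comp, cfg.nutrient.c_max)

        if cfg.fix_phase:
            for n in range(self.n_nodes):
                add(n, phi_comp, state_init.phi[n])

        if cfg.fix_displacement:
            for n in range(self.n_nodes):
                for d in range(dim):
                    add(n, d, 0.0)
        elif mesh.meta.get("kind") in ("annulus", "tube"):
            n0 = self._nearest_node(0.0)
            n90 = self._nearest_node(0.5 * np.pi)
            n180 = self._nearest_node(np.pi)
            if dim == 2:
                add(n0, 1, 0.0)
                add(n180, 1, 0.0)
                add(n90, 0, 0.0)
            else:
                add(n0, 1, 0.0); add(n0, 2, 0.0)
                add(n180, 1, 0.0); add(n180, 2, 0.0)
                add(n90, 0, 0.0); add(n90, 2, 0.0)

        idx = np.asarray(idx, dtype=int)
        val = np.asarray(val, dtype=float)
        order = np.argsort(idx)
        return idx[order], val[order]

    # ------------------------------------------------------------------
    # assembly
    # ------------------------------------------------------------------
    def _total_F(self, u_elem):
        """Total deformation gradient (3x3-embedded) at Gauss points."""
        H = np.einsum("eni,egnj->egij", u_elem, self.basis.dN_dx)
        E, G = H.shape[:2]
        F = np.zeros((E, G, 3, 3))
        F[..., :self.dim, :self.dim] = H
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        return F

    def _piola(self, F, Fg_inv, Jg):
        """Total first Piola stress P(F) = Jg * P_e(F Fg^-1) Fg^-T."""
        F_e = np.einsum("egij,egjk->egik", F, Fg_inv)
        J_e = np.linalg.det(F_e)
        if np.any(J_e <= 0.0):
            raise _StepFailure("element inversion (det F_e <= 0)")
        P_e = mech.elastic_piola_stress(F_e, self.fiber_gp, self.config.material)
        # Fg is diagonal/isotropic: Fg^-T = Fg^-1
        return Jg[..., None, None] * np.einsum("egij,egjk->egik", P_e, Fg_inv)

    def _mech_blocks(self, u_elem, alpha):
        dim = self.dim
        Fg = mech.growth_tensor(alpha, plane=(dim == 2))
        Fg_inv = np.linalg.inv(Fg)
        Jg = np.linalg.det(Fg)
        F = self._total_F(u_elem)
        P = self._piola(F, Fg_inv, Jg)
        w = self.basis.detJxW
        r_u = np.einsum("egij,egnj,eg->eni", P[..., :dim, :dim],
                        self.basis.dN_dx, w)

        # material+geometric tangent dP/dF by central differences per GP
        h = 1.0e-6
        E, G = F.shape[:2]
        A = np.empty((E, G, dim, dim, dim, dim))
        for k in range(dim):
            for l in range(dim):
                Fp = F.copy(); Fp[..., k, l] += h
                Fm = F.copy(); Fm[..., k, l] -= h
                Pp = self._piola(Fp, Fg_inv, Jg)
                Pm = self._piola(Fm, Fg_inv, Jg)
                A[..., k, l] = (Pp - Pm)[..., :dim, :dim] / (2.0 * h)
        K_uu = np.einsum("egijkl,egnj,egml,eg->enimk", A, self.basis.dN_dx,
                         self.basis.dN_dx, w)
        nn = self.basis.nn
        K_uu = K_uu.reshape(E, nn * dim, nn * dim, order="C").copy()
        # reshape: (n,i) and (m,k) flatten in node-major component-minor order,
        # matching edof_u layout
        return r_u.reshape(E, nn * dim), K_uu

    def _pressure_blocks(self, u, pressure):
        """Follower-load residual (negated external force) and its tangent."""
        facets = self.press_facets
        x = self.mesh.node_coords + u
        if self.dim == 2:
            xa = x[facets[:, 0]]
            xb = x[facets[:, 1]]
            v = xb - xa                                  # CCW tangent, |v| = edge length
            nvec = np.column_stack([-v[:, 1], v[:, 0]])  # outward of the solid
            f = -0.5 * pressure * nvec                   # per node a and b
            r = np.concatenate([-f, -f], axis=1)         # residual -= f_ext
            R90 = np.array([[0.0, -1.0], [1.0, 0.0]])
            # d f_a / d u_a = +p/2 R90, d f_a / d u_b = -p/2 R90 (same for f_b)
            Kf = np.zeros((facets.shape[0], 4, 4))
            Kf[:, 0:2, 0:2] = -0.5 * pressure * R90      # -(df/du) contributions
            Kf[:, 0:2, 2:4] = +0.5 * pressure * R90
            Kf[:, 2:4, 0:2] = -0.5 * pressure * R90
            Kf[:, 2:4, 2:4] = +0.5 * pressure * R90
            return r, Kf
        # 3D: quad facets, 2x2 Gauss on the deformed surface
        N, dN, w = self._facet_N, self._facet_dN, self._facet_w
        xf = x[facets]                                   # (F, 4, 3)
        a_xi = np.einsum("gn,fni->fgi", dN[..., 0], xf)
        a_eta = np.einsum("gn,fni->fgi", dN[..., 1], xf)
        nda = np.cross(a_xi, a_eta)                      # outward of solid
        f = -pressure * np.einsum("gn,fgi,g->fni", N, nda, w)
        r = -f.reshape(facets.shape[0], -1)
        # tangent: d(nda)/du_m = dN_m,xi (e_k x a_eta) + dN_m,eta (a_xi x e_k)
        t1 = np.einsum("akc,fgc->fgak", _EPS3, a_eta)    # (e_k x a_eta)_a
        t2 = -np.einsum("akc,fgc->fgak", _EPS3, a_xi)    # (a_xi x e_k)_a
        dnda = (np.einsum("gm,fgak->fgmak", dN[..., 0], t1)
                + np.einsum("gm,fgak->fgmak", dN[..., 1], t2))
        dF = -pressure * np.einsum("gn,fgmak,g->fnamk", N, dnda, w)
        nf = facets.shape[1]
        Kf = -dF.reshape(facets.shape[0], nf * 3, nf * 3)
        return r, Kf

    def assemble(self, x: np.ndarray, phi_prev_gp: np.ndarray,
                 alpha: np.ndarray, dt: float, pressure: float,
                 advect_gp: np.ndarray | None):
        """Global residual and tangent at the packed state vector ``x``.

        The lagged quantities (``alpha``, ``advect_gp``) contribute no tangent
        blocks; the surviving advective phi-coupling and the phase-dependent
        diffusivity make the matrix unsymmetric.
        """
        cfg = self.config
        mesh, basis = self.mesh, self.basis
        dim, ndpn = self.dim, self.ndpn
        u = x.reshape(self.n_nodes, ndpn)[:, :dim]
        c = x.reshape(self.n_nodes, ndpn)[:, dim]
        phi = x.reshape(self.n_nodes, ndpn)[:, dim + 1]
        elems = mesh.elements
        u_elem = u[elems]
        c_elem = c[elems]
        phi_elem = phi[elems]

        R = np.zeros(self.n_dof)
        data_blocks, rows_blocks, cols_blocks = [], [], []

        # fully clamped fields contribute identity Dirichlet rows only, so
        # their element integrals can be skipped wholesale
        if not cfg.fix_displacement:
            r_u, K_uu = self._mech_blocks(u_elem, alpha)
            np.add.at(R, self.edof_u, r_u)
            data_blocks.append(K_uu.ravel())
            rows_blocks.append(self.idx_uu[0])
            cols_blocks.append(self.idx_uu[1])

            if pressure != 0.0 and self.press_facets is not None:
                r_p, K_p = self._pressure_blocks(u, pressure)
                np.add.at(R, self.press_dofs, r_p)
                data_blocks.append(K_p.ravel())
                rows_blocks.append(self.idx_press[0])
                cols_blocks.append(self.idx_press[1])

        phi_gp = np.einsum("gn,en->eg", basis.N, phi_elem)
        if not cfg.freeze_nutrient:
            r_c = nutr.nutrient_weak_residual(c_elem, phi_gp, basis,
                                              cfg.nutrient, cfg.solver.k_c)
            np.add.at(R, self.edof_c, r_c)
            K_cc, K_cphi = nutr.nutrient_element_matrices(phi_gp, c_elem, basis,
                                                          cfg.nutrient, cfg.solver.k_c)
            data_blocks += [K_cc.ravel(), K_cphi.ravel()]
            rows_blocks += [self.idx_cc[0], self.idx_cphi[0]]
            cols_blocks += [self.idx_cc[1], self.idx_cphi[1]]

        if not cfg.fix_phase:
            r_phi = infl.phasefield_weak_residual(phi_elem, phi_prev_gp, dt, basis,
                                                  cfg.phasefield, advect_gp,
                                                  cfg.solver.k_phi)
            np.add.at(R, self.edof_phi, r_phi)
            K_pp = infl.phasefield_element_matrix(phi_elem, dt, basis,
                                                  cfg.phasefield, advect_gp,
                                                  cfg.solver.k_phi)
            data_blocks.append(K_pp.ravel())
            rows_blocks.append(self.idx_phiphi[0])
            cols_blocks.append(self.idx_phiphi[1])

        K = sp.coo_matrix(
            (np.concatenate(data_blocks),
             (np.concatenate(rows_blocks), np.concatenate(cols_blocks))),
            shape=(self.n_dof, self.n_dof)).tocsr()
        return R, K

    # ------------------------------------------------------------------
    # Newton / time stepping
    # ------------------------------------------------------------------
    def _lagged_advection(self, state: FieldState):
        """R_s H(c - c_cri) * unit ascent direction, from the previous step."""
        cfg = self.config
        if cfg.phasefield.source_rate == 0.0:
            return None
        basis, elems = self.basis, self.mesh.elements
        grad_c = basis.gradient(state.c, elems)
        c_gp = basis.interpolate(state.c, elems)
        g = infl.unit_ascent_direction(grad_c, cfg.phasefield)
        H = mech.heaviside(np.maximum(c_gp, 0.0), cfg.nutrient.c_cri)
        return cfg.phasefield.source_rate * H[..., None] * g

    def newton_solve(self, x0: np.ndarray, phi_prev_gp, alpha, dt, pressure,
                     advect_gp, dirichlet):
        """Newton iteration on the monolithic system; returns (x, residual history)."""
        cfg = self.config.solver
        idx, val = dirichlet
        free = np.ones(self.n_dof)
        free[idx] = 0.0
        D = sp.diags(free)
        Ifix = sp.diags(1.0 - free)

        def residual(xv):
            R, K = self.assemble(xv, phi_prev_gp, alpha, dt, pressure, advect_gp)
            R = free * R
            R[idx] = xv[idx] - val
            return R, K

        x = x0.copy()
        R, K = residual(x)
        norm = float(np.linalg.norm(R))
        history = [norm]
        for it in range(cfg.newton_max_iter + 1):
            if not np.isfinite(norm):
                raise _StepFailure("non-finite residual")
            if norm < cfg.newton_tol:
                return x, history
            if it == cfg.newton_max_iter:
                break
            Kmod = (D @ K + Ifix).tocsc()
            dx = spla.spsolve(Kmod, -R)
            if not np.all(np.isfinite(dx)):
                raise _StepFailure("linear solve failed")
            # backtracking guard against the non-smooth terms (penalty,
            # Macaulay kinks): accept the longest step that does not grow
            # the residual by more than a whisker
            lam = 1.0
            for _ in range(6):
                try:
                    R_new, K_new = residual(x + lam * dx)
                except _StepFailure:
                    lam *= 0.5
                    continue
                n_new = float(np.linalg.norm(R_new))
                if n_new <= max(1.001 * norm, cfg.newton_tol) or lam < 0.2:
                    break
                lam *= 0.5
            else:
                raise _StepFailure("line search failed")
            x = x + lam * dx
            R, K, norm = R_new, K_new, n_new
            history.append(norm)
        raise _StepFailure(f"Newton did not converge in {cfg.newton_max_iter} "
                           f"iterations (residual {history[-1]:.3e})")

    def _pressure_at(self, t: float) -> float:
        s = self.config.solver
        if s.p_max == 0.0:
            return 0.0
        if s.p_ramp_time > 0.0:
            return s.p_max * min(t / s.p_ramp_time, 1.0)
        return s.p_max

    def _pack(self, state: FieldState) -> np.ndarray:
        x = np.zeros((self.n_nodes, self.ndpn))
        x[:, :self.dim] = state.u
        x[:, self.dim] = state.c
        x[:, self.dim + 1] = state.phi
        return x.ravel()

    def _unpack(self, x: np.ndarray, alpha, t) -> FieldState:
        xm = x.reshape(self.n_nodes, self.ndpn)
        return FieldState(u=xm[:, :self.dim].copy(), c=xm[:, self.dim].copy(),
                          phi=xm[:, self.dim + 1].copy(), alpha=alpha.copy(),
                          time=t)

    # ------------------------------------------------------------------
    def seed_phi(self) -> np.ndarray:
        """Initial inflammation: a smooth bump at mid-wall, azimuth S/r_mid.

        The profile is the stationary interface shape ``(1 - tanh(k d))/2``
        so the Allen-Cahn relaxation transient stays small.
        """
        cfg = self.config
        phi0 = np.zeros(self.n_nodes)
        if not cfg.seed_lesion:
            return phi0
        geom = cfg.geometry
        th = geom.occlusion_arc / geom.mid_radius
        center = np.array([geom.mid_radius * np.cos(th),
                           geom.mid_radius * np.sin(th)])
        coords = self.mesh.node_coords
        if self.dim == 2:
            d = np.linalg.norm(coords - center, axis=1)
        else:
            c3 = np.array([center[0], center[1], 0.5 * geom.length])
            d = np.linalg.norm(coords - c3, axis=1)
        pf = cfg.phasefield
        k_prof = 2.0 * np.sqrt(2.0) * pf.barrier / pf.interface
        return np.clip(0.5 * (1.0 - np.tanh(k_prof * (d - cfg.lesion_seed_radius))),
                       0.0, 1.0)

    def initial_state(self, phi0: np.ndarray | None = None,
                      c0: np.ndarray | None = None) -> FieldState:
        """State at t=0: undeformed, seeded phase field, steady nutrient."""
        E, G = self.basis.detJxW.shape
        alpha0 = np.zeros((E, G))
        phi0 = self.seed_phi() if phi0 is None else np.asarray(phi0, dtype=float)
        if c0 is None:
            c0 = np.full(self.n_nodes, self.config.nutrient.c_max)
        state = FieldState(u=np.zeros((self.n_nodes, self.dim)),
                           c=np.asarray(c0, dtype=float).copy(),
                           phi=phi0.copy(), alpha=alpha0, time=0.0)
        if self.config.freeze_nutrient:
            return state
        # steady nutrient solve at the seeded phase field (u, phi clamped)
        frozen = replace(self.config, fix_displacement=True, fix_phase=True)
        sub = object.__new__(Simulation)
        sub.__dict__.update(self.__dict__)
        sub.config = frozen
        dirichlet = sub.dirichlet_dofs(state)
        phi_prev_gp = self.basis.interpolate(phi0, self.mesh.elements)
        x, _ = sub.newton_solve(self._pack(state), phi_prev_gp, alpha0,
                                1.0, 0.0, None, dirichlet)
        state.c = x.reshape(self.n_nodes, self.ndpn)[:, self.dim].copy()
        return state

    def courant_dt(self) -> float:
        """Cap the step so the advective Courant number R_s dt / h <= 1/2."""
        rs = self.config.phasefield.source_rate
        h = self.mesh.meta.get("h", self.config.geometry.mesh_size)
        return np.inf if rs == 0.0 else 0.5 * h / rs

    def run(self, phi0=None, c0=None, record_states: bool = True) -> SimulationResult:
        """Backward-Euler pseudo-time loop.

        Per step: freeze lagged quantities at step ``n``, Newton-solve the
        monolithic ``[u, c, phi]`` system, then advance ``alpha`` at the
        Gauss points with the converged inflammation (staggered update).
        Deterministic for a fixed configuration and seed.
        """
        from . import postproc

        cfg = self.config
        t_start = _time.perf_counter()
        state = self.initial_state(phi0, c0)
        dirichlet = self.dirichlet_dofs(state)
        area0 = postproc.lumen_area(self.mesh, np.zeros_like(state.u)) \
            if self.mesh.meta.get("kind") in ("annulus", "tube") else np.nan

        result = SimulationResult(mesh=self.mesh, config=cfg, trees=self.trees)
        series = {k: [] for k in ("time", "lumen_area_um2", "stenosis_pct",
                                  "min_c", "max_phi", "max_p1_kPa")}
        newton_log = []

        def record(st: FieldState):
            if record_states:
                result.states.append(st.copy())
            series["time"].append(st.time)
            if np.isfinite(area0):
                area = postproc.lumen_area(self.mesh, st.u)
                series["lumen_area_um2"].append(area)
                series["stenosis_pct"].append(100.0 * (1.0 - area / area0))
            else:
                series["lumen_area_um2"].append(np.nan)
                series["stenosis_pct"].append(np.nan)
            series["min_c"].append(float(np.min(st.c)))
            series["max_phi"].append(float(np.max(st.phi)))
            sig = self.cauchy_stress_field(st)
            series["max_p1_kPa"].append(float(np.max(
                postproc.principal_stresses(sig))) if sig is not None else np.nan)

        record(state)
        sol = cfg.solver
        dt_base = min(sol.dt, self.courant_dt())
        t = 0.0
        step = 0
        while t < sol.t_end - 1.0e-12:
            dt_target = min(dt_base, sol.t_end - t)
            remaining = dt_target
            dt_try = dt_target
            halvings = 0
            while remaining > 1.0e-12:
                advect = self._lagged_advection(state)
                phi_prev_gp = self.basis.interpolate(state.phi, self.mesh.elements)
                pressure = self._pressure_at(t + dt_try)
                try:
                    x, hist = self.newton_solve(self._pack(state), phi_prev_gp,
                                                state.alpha, dt_try, pressure,
                                                advect, dirichlet)
                except _StepFailure as err:
                    halvings += 1
                    if halvings > sol.step_halving_max:
                        raise SolverError(
                            f"step at t={t:.4g} failed after "
                            f"{sol.step_halving_max} halvings: {err}") from err
                    dt_try *= 0.5
                    continue
                t += dt_try
                remaining -= dt_try
                newton_log.append({"t": t, "dt": dt_try, "iters": len(hist) - 1,
                                   "residuals": hist})
                phi_gp = self.basis.interpolate(
                    x.reshape(self.n_nodes, self.ndpn)[:, self.dim + 1],
                    self.mesh.elements)
                alpha_new = mech.update_alpha(state.alpha, phi_gp, dt_try,
                                              self.config.growth)
                state = self._unpack(x, alpha_new, t)
                dt_try = min(dt_try, remaining) if remaining > 0 else dt_try
            step += 1
            if np.min(state.c) < -1.0e-8:
                msg = f"nutrient starvation: min c = {np.min(state.c):.3e} at t={t:.4g}"
                if msg not in self.warnings:
                    self.warnings.append(msg)
            if step % max(1, sol.save_every) == 0 or t >= sol.t_end - 1.0e-12:
                record(state)

        result.series = {k: np.asarray(v) for k, v in series.items()}
        result.log = {
            "label": cfg.label,
            "config": cfg.to_dict(),
            "newton": newton_log,
            "warnings": list(self.warnings),
            "n_dof": self.n_dof,
            "n_elements": self.mesh.n_elements,
            "wall_time_s": _time.perf_counter() - t_start,
            "vv_seed": cfg.vasa_vasorum.seed if cfg.enable_vv else None,
            "occluded_tree": getattr(self, "occluded_tree", None),
        }
        return result

    # ------------------------------------------------------------------
    def cauchy_stress_field(self, state: FieldState) -> np.ndarray | None:
        """Cauchy stress at all Gauss points for a given state, (E, ngp, 3, 3)."""
        u_elem = state.u[self.mesh.elements]
        F = self._total_F(u_elem)
        Fg = mech.growth_tensor(state.alpha, plane=(self.dim == 2))
        F_e = np.einsum("egij,egjk->egik", F, np.linalg.inv(Fg))
        if np.any(np.linalg.det(F_e) <= 0):
            return None
        return mech.cauchy_stress(F_e, self.fiber_gp, self.config.material)
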