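"""Allen-Cahn phase-field physics of the inflammation front.

The inflammation indicator ``phi`` (0 healthy, 1 inflamed) evolves by
non-conservative Allen-Cahn dynamics

    dphi/dt = -M f'(phi) + eps^2 lap(phi) + S(phi, c)

with the double-well ``f(phi) = 16 M phi^2 (1-phi)^2`` (note the barrier
parameter appears both inside ``f`` and as the mobility prefactor, so the
effective barrier stiffness scales as M^2 — this convention is kept
deliberately) and the scarcity-seeking source

    S = R_s H(c - c_cri) (grad phi . grad c) / |grad c| ,

an advection of the interface with speed ``R_s`` along ``-grad c``, i.e.
toward nutrient-starved tissue, gated off where the nutrient is plentiful.
A quadratic Macaulay penalty keeps ``phi`` in [0, 1].
"""

from __future__ import annotations

import numpy as np

from .mechanics import heaviside, macaulay
from .params import PhaseFieldParams


def double_well(phi, M: float):
    """``f(phi) = 16 M phi^2 (1-phi)^2`` — wells at 0 and 1, barrier M at 1/2."""
    phi = np.asarray(phi, dtype=float)
    return 16.0 * M * phi ** 2 * (1.0 - phi) ** 2


def double_well_prime(phi, M: float):
    """``f'(phi) = 32 M phi (1-phi)(1-2 phi)``."""
    phi = np.asarray(phi, dtype=float)
    return 32.0 * M * phi * (1.0 - phi) * (1.0 - 2.0 * phi)


def double_well_second(phi, M: float):
    phi = np.asarray(phi, dtype=float)
    return 32.0 * M * (1.0 - 6.0 * phi + 6.0 * phi ** 2)


def penalty_prime(phi, k_p: float = 1.0):
    """Derivative of the boundedness penalty ``P = <phi-1>^2 + <-phi>^2``.

    Zero inside [0, 1]; ``2 k_p (phi-1)`` above, ``2 k_p phi`` below.
    """
    phi = np.asarray(phi, dtype=float)
    return k_p * (2.0 * macaulay(phi - 1.0) - 2.0 * macaulay(-phi))


def penalty_second(phi, k_p: float = 1.0):
    phi = np.asarray(phi, dtype=float)
    return k_p * 2.0 * ((phi > 1.0) | (phi < 0.0)).astype(float)


def source_term(grad_phi, grad_c, c, pf: PhaseFieldParams, c_cri: float):
    """Scarcity-driven interface advection source at quadrature points.

    ``S = R_s H(c - c_cri) (grad phi . g)`` with the unit ascent direction
    ``g = grad c / max(|grad c|, delta_g)``; the floor removes the singular
    zero-gradient case (no preferred direction -> no advection).
    ``c`` is clamped at 0 inside the gate so that numerically negative
    (starved) concentrations still count as scarce.
    """
    grad_phi = np.asarray(grad_phi, dtype=float)
    g = unit_ascent_direction(grad_c, pf)
    H = heaviside(np.maximum(np.asarray(c, dtype=float), 0.0), c_cri)
    return pf.source_rate * H * np.einsum("...i,...i->...", grad_phi, g)


def unit_ascent_direction(grad_c, pf: PhaseFieldParams):
    """``grad c / max(|grad c|, delta_g)`` (zero-safe unit vector)."""
    grad_c = np.asarray(grad_c, dtype=float)
    norm = np.sqrt(np.einsum("...i,...i->...", grad_c, grad_c))
    return grad_c / np.maximum(norm, pf.grad_floor)[..., None]


def phasefield_weak_residual(phi_elem, phi_prev_gp, dt, basis,
                             pf: PhaseFieldParams, advect_gp=None,
                             k_phi: float = 1.0):
    """Element residual of the backward-Euler Allen-Cahn weak form.

    ``r_a = K_phi sum_gp [eps^2 grad phi . grad N_a + M f'(phi) N_a
    + (phi - phi^{n-1})/dt N_a - S N_a + K_p P'(phi) N_a] detJ w``

    ``advect_gp`` (E, ngp, dim) is the lagged advection vector
    ``R_s H(c - c_cri) grad c / |grad c|`` frozen at the previous converged
    nutrient field; the source is its dot product with the *current* phase
    gradient.  The boundary flux of ``phi`` is naturally zero.
    """
    w = basis.detJxW
    grad_phi = np.einsum("egni,en->egi", basis.dN_dx, phi_elem)
    phi_gp = np.einsum("gn,en->eg", basis.N, phi_elem)
    r = pf.interface ** 2 * np.einsum("egi,egni,eg->en", grad_phi, basis.dN_dx, w)
    bulk = (pf.barrier * double_well_prime(phi_gp, pf.barrier)
            + (phi_gp - phi_prev_gp) / dt
            + penalty_prime(phi_gp, pf.penalty))
    if advect_gp is not None:
        bulk = bulk - np.einsum("egi,egi->eg", advect_gp, grad_phi)
    r += np.einsum("eg,gn,eg->en", bulk, basis.N, w)
    return k_phi * r


def phasefield_element_matrix(phi_elem, dt, basis, pf: PhaseFieldParams,
                              advect_gp=None, k_phi: float = 1.0):
    """Tangent of the phase-field residual w.r.t. nodal phi, (E, nn, nn).

    ``advect_gp`` (E, ngp, dim) is the lagged advection direction
    ``R_s H g`` whose dot with the trial-function gradient forms the
    unsymmetric advective block.
    """
    w = basis.detJxW
    phi_gp = np.einsum("gn,en->eg", basis.N, phi_elem)
    K = pf.interface ** 2 * np.einsum("egni,egmi,eg->enm", basis.dN_dx, basis.dN_dx, w)
    diag = (pf.barrier * double_well_second(phi_gp, pf.barrier)
            + 1.0 / dt + penalty_second(phi_gp, pf.penalty))
    K += np.einsum("eg,gn,gm,eg->enm", diag, basis.N, basis.N, w)
    if advect_gp is not None:
        K -= np.einsum("egi,egmi,gn,eg->enm", advect_gp, basis.dN_dx, basis.N, w)
    return k_phi * K
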