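"""Steady diffusion-reaction transport of the nutrient in the wall.

Strong form: ``div(D(phi) grad c) - R_c = 0`` with the uniform consumption
sink ``R_c`` and a diffusivity that degrades linearly with inflammation.  The
diffusion time scale is far below the inflammation time scale, so no
transient term appears and the concentration is in steady state at every
pseudo-time step.
"""

from __future__ import annotations

import numpy as np

from .params import NutrientParams


def diffusivity(phi, p: NutrientParams):
    """Linear healthy/inflamed interpolation ``D = phi D_min + (1-phi) D_max``.

    ``phi`` is clamped to [0, 1] before evaluation.
    """
    phi = np.clip(np.asarray(phi, dtype=float), 0.0, 1.0)
    return phi * p.d_min + (1.0 - phi) * p.d_max


def diffusivity_dphi(phi, p: NutrientParams):
    """Derivative of :func:`diffusivity` w.r.t. the (unclamped) phase value."""
    phi = np.asarray(phi, dtype=float)
    inside = ((phi >= 0.0) & (phi <= 1.0)).astype(float)
    return inside * (p.d_min - p.d_max)


def nutrient_weak_residual(c_elem, phi_gp, basis, p: NutrientParams,
                           k_c: float = 1.0):
    """Element residual of the nutrient weak form.

    ``r_a = K_c sum_gp [D(phi) grad c . grad N_a + R_c N_a] detJ w``

    Parameters are Gauss-point phase values ``phi_gp`` (E, ngp), the nodal
    concentration restricted per element ``c_elem`` (E, nn) and the
    precomputed :class:`~atherofem.fem.ElementBasis`.  Returns (E, nn).
    """
    grad_c = np.einsum("egni,en->egi", basis.dN_dx, c_elem)
    D = diffusivity(phi_gp, p)
    w = basis.detJxW
    r = np.einsum("eg,egi,egni,eg->en", D, grad_c, basis.dN_dx, w)
    r += p.consumption * np.einsum("gn,eg->en", basis.N, w)
    return k_c * r


def nutrient_element_matrices(phi_gp, c_elem, basis, p: NutrientParams,
                              k_c: float = 1.0):
    """Tangent blocks of the nutrient equation.

    Returns ``(K_cc, K_cphi)`` with shapes (E, nn, nn): the diffusion
    stiffness at the current (clamped) phase value and the coupling from the
    phase-dependent diffusivity.
    """
    w = basis.detJxW
    D = diffusivity(phi_gp, p)
    K_cc = np.einsum("eg,egni,egmi,eg->enm", D, basis.dN_dx, basis.dN_dx, w)
    grad_c = np.einsum("egni,en->egi", basis.dN_dx, c_elem)
    dD = diffusivity_dphi(phi_gp, p)
    K_cphi = np.einsum("eg,egi,egni,gm,eg->enm", dD, grad_c, basis.dN_dx, basis.N, w)
    return k_c * K_cc, k_c * K_cphi
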