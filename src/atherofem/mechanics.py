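"""Constitutive law and growth kinematics of the artery wall.

The wall is a Holzapfel-Gasser-Ogden (HGO) type anisotropic hyperelastic
solid: a neo-Hookean matrix, an exponentially stiffening collagen-fiber term
that is active only in tension (Macaulay bracket on the fiber invariant), and
a quadratic volumetric term.  Inflammatory overgrowth enters through the
multiplicative split ``F = F_e F_g`` with the isotropic growth tensor
``F_g = (1+alpha) I`` and the Gauss-point internal variable ``alpha``.

All tensor quantities are 3x3; plane-strain 2D states embed with
``F[...,2,2] = 1``.  Every function is vectorized over leading axes.
"""

from __future__ import annotations

import warnings

import numpy as np

from .params import GrowthParams, MaterialParams

_I3 = np.eye(3)


def macaulay(x):
    """Ramp (Macaulay bracket): ``x`` if ``x >= 0`` else 0."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def heaviside(x, x_cri):
    """Threshold gate: 1 where ``x <= x_cri``, else 0 (active at-or-below).

    This inverted convention makes the gate fire under *scarcity*: the
    inflammation source activates where the nutrient has dropped to or below
    its critical value, and growth proceeds while ``alpha`` is still at or
    below its cap.
    """
    return (np.asarray(x, dtype=float) <= x_cri).astype(float)


def fiber_direction(theta_az, theta_el):
    """Unit tangent of a collagen-fiber helix.

    ``theta_az`` is the circumferential location of the point, ``theta_el``
    the constant helix elevation; ``theta_el = 0`` gives purely circumferential
    fibers, ``pi/2`` purely axial ones.
    """
    theta_az = np.asarray(theta_az, dtype=float)
    theta_el = np.asarray(theta_el, dtype=float)
    shape = np.broadcast_shapes(theta_az.shape, theta_el.shape)
    n = np.empty(shape + (3,))
    n[..., 0] = -np.cos(theta_el) * np.sin(theta_az)
    n[..., 1] = np.cos(theta_el) * np.cos(theta_az)
    n[..., 2] = np.sin(theta_el) + np.zeros(shape)
    return n


def deformation_gradient(grad_u: np.ndarray) -> np.ndarray:
    """F from the *spatial* displacement gradient: ``F = (I - grad u)^{-1}``.

    Raises ``np.linalg.LinAlgError`` when an element has inverted
    (``I - grad u`` singular); the Newton driver catches this and halves the
    step.
    """
    grad_u = np.asarray(grad_u, dtype=float)
    A = _I3 - grad_u
    return np.linalg.inv(A)


def growth_tensor(alpha, plane: bool = False) -> np.ndarray:
    """Isotropic growth tensor ``F_g = (1+alpha) I``.

    With ``plane=True`` (2D cross-section, plane strain) the growth acts
    in-plane only and the out-of-plane stretch stays 1.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= -1.0):
        raise ValueError("growth variable must satisfy alpha > -1")
    F_g = np.zeros(alpha.shape + (3, 3))
    s = 1.0 + alpha
    F_g[..., 0, 0] = s
    F_g[..., 1, 1] = s
    F_g[..., 2, 2] = 1.0 if plane else s
    return F_g


def invariants(F_e: np.ndarray, n_fiber: np.ndarray):
    """Isochoric invariants ``(I1e, I4e, J_e)`` of the elastic deformation.

    ``C_bar = J^{-2/3} F^T F``; ``I1e = tr(C_bar)``; ``I4e = n . C_bar . n``
    with the reference fiber direction ``n``.
    """
    F_e = np.asarray(F_e, dtype=float)
    J = np.linalg.det(F_e)
    if np.any(J <= 0.0):
        raise ValueError("non-positive elastic Jacobian")
    C = np.einsum("...ki,...kj->...ij", F_e, F_e)
    scale = J ** (-2.0 / 3.0)
    I1 = scale * np.trace(C, axis1=-2, axis2=-1)
    I4 = scale * np.einsum("...i,...ij,...j->...", n_fiber, C, n_fiber)
    return I1, I4, J


def _energy_terms(F_e, n_fiber, mat: MaterialParams):
    """Shared kinematic quantities for energy/stress evaluation."""
    F_e = np.asarray(F_e, dtype=float)
    n_fiber = np.asarray(n_fiber, dtype=float)
    J = np.linalg.det(F_e)
    if np.any(J <= 0.0):
        raise ValueError("non-positive elastic Jacobian")
    Finv = np.linalg.inv(F_e)
    FinvT = np.swapaxes(Finv, -1, -2)
    C = np.einsum("...ki,...kj->...ij", F_e, F_e)
    trC = np.trace(C, axis1=-2, axis2=-1)
    scale = J ** (-2.0 / 3.0)
    I1iso = scale * trC
    I4iso = scale * np.einsum("...i,...ij,...j->...", n_fiber, C, n_fiber)
    return F_e, n_fiber, J, FinvT, trC, I1iso, I4iso


def _fiber_exponent(I1iso, I4iso, mat: MaterialParams):
    Q = mat.fiber_exponent * (
        mat.dispersion * macaulay(I4iso - 1.0) ** 2
        + (1.0 - mat.dispersion) * (I1iso - 3.0) ** 2
    )
    clipped = Q > mat.exp_clip
    if np.any(clipped):
        warnings.warn(
            "fiber energy exponent clipped (fiber over-extension)",
            RuntimeWarning, stacklevel=3,
        )
    return np.minimum(Q, mat.exp_clip), clipped


def free_energy(F_e, n_fiber, mat: MaterialParams):
    """HGO free energy density [kPa] per unit intermediate (grown) volume.

    ``Psi = mu/2 (I1m - 3) + eta/beta exp(Q) + kappa_vol (J-1)^2 - mu log J``
    with ``Q = beta [rho <I4e-1>^2 + (1-rho)(I1e-3)^2]`` on the isochoric
    invariants.  By default the matrix term uses the full first invariant
    ``I1m = tr(F^T F)`` so that the log term cancels at identity and the
    unloaded state is exactly stress free; the all-isochoric variant is
    selectable via ``MaterialParams.isochoric_matrix_term``.
    """
    F_e, n_fiber, J, FinvT, trC, I1iso, I4iso = _energy_terms(F_e, n_fiber, mat)
    I1m = I1iso if mat.isochoric_matrix_term else trC
    Q, _ = _fiber_exponent(I1iso, I4iso, mat)
    psi = 0.5 * mat.shear_modulus * (I1m - 3.0)
    if mat.fiber_stiffness > 0.0:
        psi = psi + (mat.fiber_stiffness / mat.fiber_exponent) * np.exp(Q)
    psi = psi + mat.kappa_vol * (J - 1.0) ** 2 - mat.shear_modulus * np.log(J)
    return psi


def elastic_piola_stress(F_e, n_fiber, mat: MaterialParams):
    """First Piola stress ``P_e = dPsi/dF_e`` (analytic)."""
    F_e, n_fiber, J, FinvT, trC, I1iso, I4iso = _energy_terms(F_e, n_fiber, mat)
    mu, eta, beta, rho = (mat.shear_modulus, mat.fiber_stiffness,
                          mat.fiber_exponent, mat.dispersion)
    scale = (J ** (-2.0 / 3.0))[..., None, None]
    dI1iso = 2.0 * scale * F_e - (2.0 / 3.0) * I1iso[..., None, None] * FinvT
    if mat.isochoric_matrix_term:
        P = mu * 0.5 * dI1iso
    else:
        P = mu * F_e
    if eta > 0.0:
        Fn = np.einsum("...ij,...j->...i", F_e, n_fiber)
        dI4iso = (2.0 * scale * np.einsum("...i,...j->...ij", Fn, n_fiber)
                  - (2.0 / 3.0) * I4iso[..., None, None] * FinvT)
        Q, clipped = _fiber_exponent(I1iso, I4iso, mat)
        eQ = np.exp(Q)
        eQ = np.where(clipped, 0.0 * eQ + np.exp(mat.exp_clip), eQ)
        coef4 = 2.0 * rho * macaulay(I4iso - 1.0)
        coef1 = 2.0 * (1.0 - rho) * (I1iso - 3.0)
        # at the clip the energy is frozen; keep the gradient of the clipped
        # (constant) branch zero to stay consistent with free_energy
        live = (~clipped).astype(float)[..., None, None]
        P = P + eta * live * eQ[..., None, None] * (
            coef4[..., None, None] * dI4iso + coef1[..., None, None] * dI1iso
        )
    coefJ = 2.0 * mat.kappa_vol * (J - 1.0) * J - mu
    P = P + coefJ[..., None, None] * FinvT
    return P


def cauchy_stress(F_e, n_fiber, mat: MaterialParams):
    """Cauchy stress ``sigma = (1/J_e) P_e F_e^T`` [kPa], symmetrized."""
    F_e = np.asarray(F_e, dtype=float)
    J = np.linalg.det(F_e)
    P = elastic_piola_stress(F_e, n_fiber, mat)
    sig = np.einsum("...ij,...kj->...ik", P, F_e) / J[..., None, None]
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


def update_alpha(alpha_n, phi, dt: float, gp: GrowthParams):
    """Advance the growth internal variable over one converged step.

    Integrates ``alpha_dot / (1+alpha) = k_g H(alpha - alpha_cri) phi``
    exactly over ``dt`` with the gate lagged at ``alpha_n`` and ``phi``
    clamped to [0, 1]:

    ``alpha_{n+1} = (1+alpha_n) exp(k_g phi dt) - 1``  while ``alpha_n <= alpha_cri``,
    else ``alpha_{n+1} = alpha_n``.
    """
    alpha_n = np.asarray(alpha_n, dtype=float)
    phi = np.clip(np.asarray(phi, dtype=float), 0.0, 1.0)
    active = heaviside(alpha_n, gp.cap)
    grown = (1.0 + alpha_n) * np.exp(gp.rate * phi * dt) - 1.0
    return np.where(active > 0.5, grown, alpha_n)
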