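"""HGO constitutive law, growth kinematics and the alpha update."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given
from hypothesis import strategies as st

from atherofem import mechanics as mech
from atherofem.params import GrowthParams, MaterialParams


@pytest.fixture
def mat():
    return MaterialParams()


def _random_states(rng, n=100, scale=0.2):
    out = []
    while len(out) < n:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) < 0.3:
            continue
        nf = rng.standard_normal(3)
        out.append((F, nf / np.linalg.norm(nf)))
    return out


def test_macaulay_ramp():
    assert mech.macaulay(3.0) == 3.0
    assert mech.macaulay(-2.0) == 0.0
    assert mech.macaulay(0.0) == 0.0


def test_heaviside_active_at_or_below_threshold():
    assert mech.heaviside(0.5, 1.0) == 1.0
    assert mech.heaviside(1.5, 1.0) == 0.0
    assert mech.heaviside(1.0, 1.0) == 1.0  # boundary inclusive


def test_fiber_direction_examples():
    n = mech.fiber_direction(0.0, np.pi / 3)
    assert np.allclose(n, [0.0, 0.5, np.sqrt(3) / 2])
    assert np.allclose(mech.fiber_direction(1.234, np.pi / 2), [0, 0, 1])


@given(st.floats(0, 2 * np.pi), st.floats(-np.pi / 2, np.pi / 2))
def test_fiber_direction_is_unit(az, el):
    assert np.linalg.norm(mech.fiber_direction(az, el)) == pytest.approx(1.0)


def test_deformation_gradient_examples(rng):
    assert np.allclose(mech.deformation_gradient(np.zeros((3, 3))), np.eye(3))
    g = np.diag([0.5, 0.0, 0.0])
    assert np.allclose(mech.deformation_gradient(g), np.diag([2.0, 1.0, 1.0]))
    # round trip: grad_u = I - F0^-1 recovers F0
    F0 = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
    gu = np.eye(3) - np.linalg.inv(F0)
    assert np.allclose(mech.deformation_gradient(gu), F0)


def test_invariants_examples():
    n = np.array([1.0, 0.0, 0.0])
    assert mech.invariants(np.eye(3), n) == pytest.approx((3.0, 1.0, 1.0))
    # pure dilation leaves the isochoric invariants unchanged
    I1, I4, J = mech.invariants(2.0 * np.eye(3), n)
    assert (I1, I4, J) == pytest.approx((3.0, 1.0, 8.0))
    lam = 1.3
    Fe = np.diag([lam, lam ** -0.5, lam ** -0.5])
    I1, I4, J = mech.invariants(Fe, n)
    assert J == pytest.approx(1.0)
    assert I4 == pytest.approx(lam ** 2)
    with pytest.raises(ValueError):
        mech.invariants(np.diag([1.0, 1.0, -1.0]), n)


def test_free_energy_reference_values(mat):
    n = np.array([0.0, 1.0, 0.0])
    # fiber term contributes the constant offset eta/beta at identity
    psi = mech.free_energy(np.eye(3), n, mat)
    assert psi == pytest.approx(mat.fiber_stiffness / mat.fiber_exponent)
    no_fiber = replace(mat, fiber_stiffness=0.0)
    assert mech.free_energy(np.eye(3), n, no_fiber) == pytest.approx(0.0)


def test_fiber_term_inactive_in_compression(mat):
    # uniaxial small compression along the fiber: the Macaulay bracket kills
    # the anisotropic term, so the dispersion weight is irrelevant to
    # leading order
    n = np.array([1.0, 0.0, 0.0])
    F = np.eye(3) - 1e-4 * np.outer(n, n)
    sigs = [mech.cauchy_stress(F, n, replace(mat, dispersion=rho))
            for rho in (0.0, 0.5, 1.0)]
    scale = np.abs(sigs[0]).max()
    assert np.abs(sigs[1] - sigs[0]).max() / scale < 1e-6
    assert np.abs(sigs[2] - sigs[0]).max() / scale < 1e-6


def test_stress_free_reference_for_admissible_materials(rng):
    for _ in range(20):
        m = MaterialParams(
            shear_modulus=float(rng.uniform(1, 50)),
            poisson=float(rng.uniform(0.2, 0.49)),
            fiber_stiffness=float(rng.uniform(0, 200)),
            fiber_exponent=float(rng.uniform(0.5, 3)),
            dispersion=float(rng.uniform(0, 1)),
        )
        n = rng.standard_normal(3)
        n /= np.linalg.norm(n)
        sig = mech.cauchy_stress(np.eye(3), n, m)
        assert np.abs(sig).max() < 1e-10


def test_stress_matches_finite_difference_of_energy(mat, rng):
    h = 1e-6
    for F, n in _random_states(rng, n=30):
        P = mech.elastic_piola_stress(F, n, mat)
        Pfd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                Pfd[i, j] = (mech.free_energy(Fp, n, mat)
                             - mech.free_energy(Fm, n, mat)) / (2 * h)
        assert np.abs(P - Pfd).max() / np.abs(P).max() < 1e-6


def test_objectivity_under_rotations(mat, rng):
    F = np.eye(3) + 0.15 * rng.standard_normal((3, 3))
    n = np.array([0.0, 1.0, 0.0])
    psi0 = mech.free_energy(F, n, mat)
    for _ in range(100):
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        psi = mech.free_energy(Q @ F, n, mat)
        assert abs(psi - psi0) / abs(psi0) < 1e-10
    # pure rotation gives zero stress
    Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    assert np.abs(mech.cauchy_stress(Q, n, mat)).max() < 1e-9


def test_cauchy_stress_is_symmetric(mat, rng):
    for F, n in _random_states(rng, n=10):
        s = mech.cauchy_stress(F, n, mat)
        assert np.abs(s - s.T).max() < 1e-12


def test_isotropic_small_strain_limit(rng):
    # eta = 0: uniaxial response must match linear elasticity with shear mu
    # and lambda = 2 mu nu / (1 - 2 nu), to first order in strain
    m = MaterialParams(fiber_stiffness=0.0)
    mu, nu = m.shear_modulus, m.poisson
    lam = 2.0 * mu * nu / (1.0 - 2.0 * nu)
    eps = 1e-4
    n = np.array([0.0, 1.0, 0.0])
    E = np.diag([eps, 0.0, 0.0])
    sig = mech.cauchy_stress(np.eye(3) + E, n, m)
    sig_lin = 2.0 * mu * E + lam * np.trace(E) * np.eye(3)
    assert np.abs(sig - sig_lin).max() / np.abs(sig_lin).max() < 0.02


def test_literal_volumetric_variant_selectable():
    m = MaterialParams(literal_volumetric=True)
    assert m.kappa_vol == pytest.approx(0.49 / (10.0 * 0.02))
    # the printed coefficient no longer cancels the log term at identity
    n = np.array([0.0, 1.0, 0.0])
    sig = mech.cauchy_stress(1.2 * np.eye(3), n, replace(m, fiber_stiffness=0.0))
    assert np.isfinite(sig).all()


def test_growth_tensor_and_determinant():
    assert np.allclose(mech.growth_tensor(0.0), np.eye(3))
    Fg = mech.growth_tensor(1e-3)
    assert np.linalg.det(Fg) == pytest.approx(1.001 ** 3)
    Fg2 = mech.growth_tensor(0.1, plane=True)
    assert Fg2[2, 2] == 1.0
    assert np.linalg.det(Fg2) == pytest.approx(1.1 ** 2)
    with pytest.raises(ValueError):
        mech.growth_tensor(-1.5)


def test_growth_velocity_gradient_identity():
    # L_g = Fg_dot Fg^-1 = (alpha_dot / (1 + alpha)) I by finite differencing
    k = 0.25
    alpha = lambda t: np.exp(k * t) - 1.0
    t0, h = 1.7, 1e-6
    Fg_dot = (mech.growth_tensor(alpha(t0 + h)) - mech.growth_tensor(alpha(t0 - h))) / (2 * h)
    Lg = Fg_dot @ np.linalg.inv(mech.growth_tensor(alpha(t0)))
    alpha_dot = k * np.exp(k * t0)
    assert np.allclose(Lg, alpha_dot / (1 + alpha(t0)) * np.eye(3), rtol=1e-6)


def test_update_alpha_examples():
    gp = GrowthParams(rate=0.25, cap=1e-3)
    assert mech.update_alpha(0.0, 0.0, 0.1, gp) == 0.0          # no inflammation
    assert mech.update_alpha(5e-3, 1.0, 0.1, gp) == 5e-3        # beyond the cap
    a = mech.update_alpha(0.0, 1.0, 0.004, gp)
    assert a == pytest.approx(np.exp(0.25 * 0.004) - 1.0)


def test_update_alpha_matches_fine_step_ode():
    # alpha_dot/(1+alpha) = k phi while alpha <= cap; compare one coarse
    # exponential step against 100 fine sub-steps
    gp = GrowthParams(rate=0.25, cap=10.0)  # cap out of reach
    dt = 0.5
    coarse = mech.update_alpha(0.0, 1.0, dt, gp)
    fine = 0.0
    for _ in range(100):
        fine = mech.update_alpha(fine, 1.0, dt / 100, gp)
    assert coarse == pytest.approx(fine, rel=1e-12)
    assert coarse == pytest.approx(np.exp(0.25 * dt) - 1.0)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
def test_growth_cap_never_exceeded_by_more_than_one_increment(phis):
    gp = GrowthParams(rate=0.25, cap=1e-3)
    dt = 0.05
    a = 0.0
    bound = gp.cap + (1.0 + gp.cap) * (np.exp(gp.rate * dt) - 1.0)
    for phi in phis:
        a = float(mech.update_alpha(a, phi, dt, gp))
        assert a <= bound + 1e-15
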