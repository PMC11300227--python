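"""Material-point law: elastic limits, viscous relaxation, yield surface,
plastic flow, damage evolution and frame indifference."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

import hfevert.constitutive as cm
from hfevert.calibrate import CalibrationScales, apply_scales
from hfevert.parameters import MaterialParameters

from .conftest import random_rotation


# ----------------------------------------------------------------------
# closed-form building blocks
# ----------------------------------------------------------------------

@pytest.mark.parametrize("E,nu,mu,k", [
    (1.0, 0.0, 0.5, 1.0 / 3.0),
    (2.9, 0.3, 1.1154, 2.4167),
    (4.18, 0.3, 1.6077, 3.4833),
])
def test_elastic_moduli_closed_form(E, nu, mu, k):
    got_mu, got_k = cm.elastic_moduli(E, nu)
    assert got_mu == pytest.approx(mu, abs=1e-4)
    assert got_k == pytest.approx(k, abs=1e-4)


def test_elastic_moduli_rejects_incompressible():
    with pytest.raises(ValueError):
        cm.elastic_moduli(1.0, 0.5)
    with pytest.raises(ValueError):
        cm.elastic_moduli(1.0, -1.0)


@pytest.mark.parametrize("bvtv,expected", [
    (0.0, 0.0),
    (0.5, 0.25),
    (1.0, 1.0 + (10 - 2.9) / 2.9),
])
def test_tissue_function_values(bvtv, expected):
    assert cm.tissue_function(bvtv, 10.0, 2.9, 2.0) == pytest.approx(expected, rel=1e-12)


def test_tissue_function_continuity_at_dense_branch():
    eps = 1e-10
    below = cm.tissue_function(0.5 - eps, 10.0, 2.9, 2.0)
    above = cm.tissue_function(0.5 + eps, 10.0, 2.9, 2.0)
    assert above == pytest.approx(below, abs=1e-8)


def test_tissue_function_domain_error():
    with pytest.raises(ValueError):
        cm.tissue_function(1.2, 10.0, 2.9, 2.0)


def test_deviatoric_split_hydrostatic_and_shear():
    Td, tau, N = cm.deviatoric_split(3.7 * np.eye(3))
    assert np.allclose(Td, 0) and tau == pytest.approx(0, abs=1e-12)
    assert np.allclose(N, 0, atol=1e-12)

    s = 2.5
    T = np.zeros((3, 3)); T[0, 1] = T[1, 0] = s
    Td, tau, N = cm.deviatoric_split(T)
    assert tau == pytest.approx(s)
    # normalization identity of the direction tensor
    assert np.einsum("ij,ij->", N, N) == pytest.approx(1.0)


def test_deviatoric_split_properties(rng):
    for _ in range(20):
        A = rng.standard_normal((3, 3))
        T = A + A.T
        Td, tau, N = cm.deviatoric_split(T)
        assert abs(np.trace(Td)) < 1e-12 * max(1, abs(np.trace(T)))
        if tau > 0:
            assert np.einsum("ij,ij->", N, N) == pytest.approx(1.0)


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
def test_deviatoric_split_invariants_hypothesis(vals):
    """For any symmetric tensor: the deviator is traceless, and the
    direction tensor is unit-normalized whenever tau is appreciable."""
    a, b, c, d, e, f = vals
    T = np.array([[a, d, e], [d, b, f], [e, f, c]])
    Td, tau, N = cm.deviatoric_split(T)
    assert abs(np.trace(Td)) <= 1e-10 * max(1.0, np.abs(T).max())
    if tau > 1e-8 * max(1.0, np.abs(T).max()):
        assert np.einsum("ij,ij->", N, N) == pytest.approx(1.0, rel=1e-9)
        # reconstruction identity: T' = tau * sqrt(2) * N
        assert np.allclose(Td, tau * np.sqrt(2) * N, atol=1e-9)


@settings(max_examples=50, derandomize=True)
@given(st.floats(0.0, 1.0), st.floats(1.0, 6.0))
def test_tissue_function_monotone_hypothesis(bvtv, k_exp):
    """TF is non-negative and non-decreasing in BV/TV."""
    lo = cm.tissue_function(bvtv, 10.0, 2.9, k_exp)
    hi = cm.tissue_function(min(bvtv + 1e-3, 1.0), 10.0, 2.9, k_exp)
    assert lo >= 0.0
    assert hi >= lo - 1e-12


def test_deviatoric_split_rejects_asymmetric():
    T = np.zeros((3, 3)); T[0, 1] = 1.0
    with pytest.raises(ValueError):
        cm.deviatoric_split(T)


# ----------------------------------------------------------------------
# equilibrium branch
# ----------------------------------------------------------------------

def test_equilibrium_branch_zero_for_identity_and_rotation(params, rng):
    st = cm.MaterialState.pristine(())
    assert np.allclose(cm.equilibrium_branch_stress(st, 0.5, params), 0)
    st.F = random_rotation(rng)
    assert np.allclose(cm.equilibrium_branch_stress(st, 0.5, params), 0, atol=1e-12)


def test_equilibrium_branch_small_strain_modulus(params):
    """Axial tangent at small uniaxial stretch matches E00 (nu=0, bvtv with
    k_exp=1 and Emax=E00 so the tissue scale is bvtv itself)."""
    p = params.replace(nu=0.0, k_exp=1.0, Emax=params.E00)
    lam = 1.001
    st = cm.MaterialState.pristine(())
    st.F = np.diag([1.0, 1.0, lam])
    T = cm.equilibrium_branch_stress(st, 1.0, p)
    strain = 0.5 * (lam ** 2 - 1)  # Green-Lagrange
    E_eff = T[2, 2] / strain
    assert E_eff == pytest.approx(p.E00 * 1e3, rel=1e-3)


# ----------------------------------------------------------------------
# Maxwell branches
# ----------------------------------------------------------------------

def test_branch_zero_strain_is_fixed_point():
    z = np.zeros((3, 3))
    ev, T = cm.viscoelastic_branch_update(z, z, z, 0.1, 1.0, 1.0, 1.0, 1.0)
    assert np.allclose(ev, 0) and np.allclose(T, 0)


def test_branch_relaxation_time_constant():
    """Held deviatoric strain: stress decays as exp(-t mu/eta)."""
    eta, mu = 0.24, 300.0
    eps = np.diag([2 / 3, -1 / 3, -1 / 3]) * 1e-3
    ev = np.zeros((3, 3))
    tau_c = eta / mu
    dt = tau_c / 200
    _, T0 = cm.viscoelastic_branch_update(ev, np.zeros((3, 3)), eps, 1e-12,
                                          eta, mu, 1.0, 1.0)
    n = int(round(tau_c / dt))
    for _ in range(n):
        ev, T = cm.viscoelastic_branch_update(ev, eps, eps, dt, eta, mu, 1.0, 1.0)
    assert T[0, 0] / T0[0, 0] == pytest.approx(np.exp(-1), rel=5e-3)


def test_branch_dt_to_zero_is_elastic():
    eps = np.diag([2 / 3, -1 / 3, -1 / 3]) * 1e-3
    ev, T = cm.viscoelastic_branch_update(np.zeros((3, 3)), np.zeros((3, 3)),
                                          eps, 1e-15, 0.24, 300.0, 1.0, 1.0)
    g = 2 * 300.0 / 3
    assert np.allclose(T, g * eps, rtol=1e-6)
    assert np.allclose(ev, 0, atol=1e-12)


def test_branch_rejects_nonpositive_dt():
    z = np.zeros((3, 3))
    with pytest.raises(ValueError):
        cm.viscoelastic_branch_update(z, z, z, 0.0, 1.0, 1.0, 1.0, 1.0)


# ----------------------------------------------------------------------
# plastic flow and damage
# ----------------------------------------------------------------------

def test_plastic_stretch_rate_power_law():
    N = np.diag([2 / 3, -1 / 3, -1 / 3])
    S0 = 140.0
    assert np.allclose(cm.plastic_stretch_rate(0.0, N, S0, 18.24), 0)
    D = cm.plastic_stretch_rate(np.sqrt(3) * S0, N, S0, 18.24)
    assert np.allclose(D, N)
    D = cm.plastic_stretch_rate(0.9 * np.sqrt(3) * S0, N, S0, 18.24)
    assert np.linalg.norm(D) / np.linalg.norm(N) == pytest.approx(0.9 ** 18.24, rel=1e-9)


def test_plastic_gradient_exponential_map(rng):
    """Constant traceless flow: volume preserved and agrees with expm oracle."""
    F_ve = np.eye(3)
    F_vp = np.eye(3)
    F = np.eye(3)
    D_vp = np.diag([1.0, -0.5, -0.5]) * 1e-2
    n, dt = 50, 0.02
    for _ in range(n):
        F_vp, dk = cm.update_plastic_gradient(F_ve, F_vp, F, D_vp, dt)
    assert np.linalg.det(F_vp) == pytest.approx(1.0, abs=1e-8)
    oracle = scipy.linalg.expm(n * dt * D_vp)  # F_ve = I so L~ = D_vp
    assert np.allclose(F_vp, oracle, rtol=1e-6)


def test_plastic_gradient_zero_flow_is_identity():
    F_vp, dk = cm.update_plastic_gradient(np.eye(3), np.eye(3), np.eye(3),
                                          np.zeros((3, 3)), 1.0)
    assert np.allclose(F_vp, np.eye(3)) and dk == 0


def test_hill_normalization(params):
    """Uniaxial stress at sigma0 and pure shear at tau0 sit on the surface."""
    p = params.mpa()
    for sign, sigma0 in ((1.0, p.sigma0_plus), (-1.0, p.sigma0_minus)):
        S = np.zeros((3, 3)); S[0, 0] = sign * sigma0
        seq = cm._hill_equivalent(S, p, 1.0)
        assert seq == pytest.approx(1.0, rel=1e-12)
    S = np.zeros((3, 3)); S[0, 1] = S[1, 0] = p.tau0
    assert cm._hill_equivalent(S, p, 1.0) == pytest.approx(1.0, rel=1e-12)
    # leading 1/TF^2 factor: doubling TF halves the equivalent stress
    assert cm._hill_equivalent(S, p, 2.0) == pytest.approx(0.5, rel=1e-12)


def test_hill_tensor_matches_equivalent(params, rng):
    """6x6 Mandel tensors reproduce the closed-form quadratic form."""
    p = params.mpa()
    F_plus, F_minus = cm.hill_tensor(params, tf_scale=1.0)
    for _ in range(10):
        A = rng.standard_normal((3, 3))
        S = A + A.T
        v = np.array([S[0, 0], S[1, 1], S[2, 2],
                      np.sqrt(2) * S[1, 2], np.sqrt(2) * S[0, 2], np.sqrt(2) * S[0, 1]])
        H = F_plus if np.trace(S) > 0 else F_minus
        q = v @ H @ v
        assert np.sqrt(max(q, 0)) == pytest.approx(
            cm._hill_equivalent(S, p, 1.0), rel=1e-9)


def test_yield_value_examples(params):
    assert cm.yield_value(np.zeros((3, 3)), params, 0.0) == pytest.approx(-params.alpha)
    # hardening saturates monotonically at 1
    r = cm.damage_hardening(np.linspace(0, 50, 200), 0.5, 1.0)
    assert np.all(np.diff(r) >= 0) and r[-1] == pytest.approx(1.0, abs=1e-8)
    assert cm.damage_hardening(1.0, 0.5, 1.0) == pytest.approx(1 - 0.5 * np.e ** -1)


def test_update_damage_law():
    D, kappa = cm.update_damage(0.0, 0.0, 0.0, 10.0)
    assert D == 0.0 and kappa == 0.0
    D, kappa = cm.update_damage(0.0, 0.0, 0.1, 10.0)
    assert D == pytest.approx(1 - np.exp(-1))
    D, _ = cm.update_damage(0.0, 0.0, 1e6, 10.0)
    assert D == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cm.update_damage(0.0, 0.0, -1e-3, 10.0)


# ----------------------------------------------------------------------
# full material-point step
# ----------------------------------------------------------------------

def _compress_path(strain, n, height=1.0):
    lams = 1.0 - np.linspace(0, strain, n + 1)
    F = np.tile(np.eye(3), (n + 1, 1, 1))
    F[:, 2, 2] = lams
    return F


def test_identity_step_gives_zero_stress(params):
    st = cm.MaterialState.pristine(())
    res, st2 = cm.material_point_update(np.eye(3), 0.5, st, 0.4, params)
    assert np.allclose(res.T, 0)
    assert np.allclose(st2.F_vp, np.eye(3)) and st2.D == 0 and st2.kappa == 0


def test_objectivity_of_invariants(params, rng):
    """Rotating the deformation leaves tau, von Mises and Y unchanged."""
    strain_rate = 1e-3
    F = np.diag([1.0, 1.0, 0.97])
    dt = 0.03 / strain_rate
    st = cm.MaterialState.pristine(())
    res, _ = cm.material_point_update(F, dt, st, 0.3, params)
    R = random_rotation(rng)
    st2 = cm.MaterialState.pristine(())
    res2, _ = cm.material_point_update(R @ F, dt, st2, 0.3, params)
    assert res2.tau == pytest.approx(res.tau, rel=1e-8, abs=1e-10)
    assert res2.Y == pytest.approx(res.Y, rel=1e-8, abs=1e-10)
    vm1 = np.sqrt(1.5 * np.einsum("ij,ij->", res.T_dev, res.T_dev))
    vm2 = np.sqrt(1.5 * np.einsum("ij,ij->", res2.T_dev, res2.T_dev))
    assert vm2 == pytest.approx(vm1, rel=1e-8)


def test_branch_sum_conservation(params):
    F = np.diag([1.0, 1.0, 0.98])
    st = cm.MaterialState.pristine(())
    res, _ = cm.material_point_update(F, 1.0, st, 0.5, params)
    assert np.allclose(res.T, res.TE0 + res.TE1 + res.TE2, rtol=1e-12)


def test_elastic_domain_is_rate_independent(params):
    """Below the yield surface kappa stays at the numerical floor for any dt."""
    F = np.diag([1.0, 1.0, 0.998])  # well inside the elastic domain
    for dt in (1e-4, 1.0, 1e4):
        st = cm.MaterialState.pristine(())
        res, st = cm.material_point_update(F, dt, st, 0.3, params)
        assert res.Y < 0
        assert st.kappa <= cm.KAPPA_FLOOR


def test_monotonic_compression_softens_and_damages(params):
    """Driven far enough, the stress peaks and then decreases while damage
    and plastic strain grow monotonically within [0, 1].  nu = 0 makes
    the strain-driven path a uniaxial-stress path, so the deviatoric
    stress can actually reach the flow regime."""
    p = params.replace(nu=0.0)
    strain, n = 0.25, 120
    rate = 1e-3
    F_path = _compress_path(strain, n)
    dt = strain / rate / n
    st = cm.MaterialState.pristine(())
    stresses, kappas, damages = [], [], []
    for k in range(1, n + 1):
        res, st = cm.material_point_update(F_path[k], dt, st, 0.3, p)
        stresses.append(-res.T[2, 2])
        kappas.append(float(st.kappa))
        damages.append(float(st.D))
    kappas, damages = np.array(kappas), np.array(damages)
    assert np.all(np.diff(kappas) >= -1e-15)
    assert np.all(np.diff(damages) >= -1e-15)
    assert np.all((damages >= 0) & (damages <= 1))
    assert damages[-1] > 0.05, "damage should have started"
    peak = int(np.argmax(stresses))
    assert peak < n - 1, "stress should peak before the end of the ramp"
    assert stresses[-1] < stresses[peak]


def test_strength_scales_with_strength_family(params):
    """Halving the strength family roughly halves the stress plateau
    (uniaxial-stress path via nu = 0)."""
    strain, n, rate = 0.18, 90, 1e-3
    F_path = _compress_path(strain, n)
    dt = strain / rate / n

    def peak(p):
        st = cm.MaterialState.pristine(())
        out = []
        for k in range(1, n + 1):
            res, st = cm.material_point_update(F_path[k], dt, st, 0.3, p)
            out.append(-res.T[2, 2])
        return max(out)

    base = params.replace(nu=0.0)
    p_half = apply_scales(base, CalibrationScales(s_E=1.0, s_S=0.5))
    full, half = peak(base), peak(p_half)
    assert half == pytest.approx(0.5 * full, rel=0.15)


def test_relaxation_to_equilibrium_branch(params):
    """Under held strain the total stress approaches the equilibrium branch."""
    F = np.diag([1.0, 1.0, 0.999])
    st = cm.MaterialState.pristine(())
    res, st = cm.material_point_update(F, 1e-6, st, 1.0, params)
    p = params.mpa()
    mu1, _ = cm.elastic_moduli(p.E01, p.nu)
    t1 = p.eta01 / mu1  # slowest branch time constant
    for _ in range(100):
        res, st = cm.material_point_update(F, t1 / 10, st, 1.0, params)
    assert res.T[2, 2] == pytest.approx(res.TE0[2, 2], rel=0.01)


def test_rejects_inverted_gradient(params):
    st = cm.MaterialState.pristine(())
    with pytest.raises(cm.ConstitutiveError):
        cm.material_point_update(-np.eye(3), 1.0, st, 0.5, params)
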