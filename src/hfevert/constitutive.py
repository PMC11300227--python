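"""Material-point integration of the elastic–viscoplastic–damage bone law.

The model is a finite-strain rheological network for homogenized bone:

* multiplicative split ``F = F_ve · F_vp`` of the deformation gradient
  into a viscoelastic and a viscoplastic part;
* a Maxwell–Wiechert network in the viscoelastic part: an equilibrium
  hyperelastic branch (Green–Lagrange strain, isotropic Saint-Venant
  stiffness) in parallel with two deviatoric Maxwell branches capturing
  low- and high-rate viscous mechanisms;
* every modulus is scaled by the *tissue function* ``TF(BV/TV)`` — the
  density–elasticity power law with a dense-bone correction branch — and
  degraded by ``(1 - D)`` where ``D`` is the scalar damage;
* co-directional power-law viscoplastic flow driven by the deviatoric
  Cauchy stress magnitude, gated by a halfspacewise Hill yield surface
  with damage hardening;
* damage coupled to accumulated plastic strain through a saturating
  exponential law.

All tensor routines are vectorized: a "tensor" argument may have any
leading batch shape followed by a trailing ``(3, 3)``, so one call
updates every quadrature point of a mesh at once.

Internal units are mm–N–s–MPa; :class:`~hfevert.parameters.MaterialParameters`
converts from the GPa user boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import MaterialParameters, MaterialParametersMPa

_I3 = np.eye(3)

#: numerical floor below which accumulated plastic strain is treated as zero
KAPPA_FLOOR = 1e-12

#: largest plastic increment integrated in a single sub-step
_DGAMMA_MAX = 0.02
_MAX_SUBSTEPS = 25
#: damage level beyond which a point no longer drives sub-step refinement
#: (its stress is within round-off of zero either way)
_D_DEAD = 0.95


class ConstitutiveError(RuntimeError):
    """Raised when a material-point update cannot be completed."""


# ----------------------------------------------------------------------
# elementary pieces
# ----------------------------------------------------------------------

def elastic_moduli(E, nu):
    """Shear and bulk modulus of an isotropic solid.

    ``mu = E / (2 (1 + nu))``, ``k = E / (3 (1 - 2 nu))``.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("Young's modulus must be positive")
    nu = float(nu)
    if not (-1.0 < nu < 0.5):
        raise ValueError(f"Poisson ratio must lie in (-1, 0.5), got {nu}")
    mu = E / (2.0 * (1.0 + nu))
    k = E / (3.0 * (1.0 - 2.0 * nu))
    return mu, k


def tissue_function(bvtv, Emax, E0, k_exp):
    """Density–elasticity scale TF(BV/TV).

    ``BVTV**k`` below the dense-bone threshold 0.5; above it an extra
    term ``(Emax/E0 - 1) * ((BVTV - 0.5)/0.5)**(2k)`` ramps the scale up
    to the dense-tissue cap.  Continuous at 0.5.
    """
    b = np.asarray(bvtv, dtype=float)
    if np.any(b < 0) or np.any(b > 1):
        raise ValueError("BV/TV must lie in [0, 1]")
    base = b ** k_exp
    extra = (Emax - E0) / E0 * np.clip((b - 0.5) / 0.5, 0.0, None) ** (2.0 * k_exp)
    out = base + extra
    if np.isscalar(bvtv):
        return float(out)
    return out


def deviatoric_split(T, check_symmetry=True, atol=1e-8):
    """Split a symmetric stress into deviator, magnitude tau and direction N.

    ``tau = sqrt(0.5 tr(T'ᵀ T'))`` and ``N = T' / (tau sqrt(2))`` so that
    ``tr(Nᵀ N) = 1``.  N is the zero tensor where tau vanishes.
    """
    T = np.asarray(T, dtype=float)
    if check_symmetry:
        asym = np.abs(T - np.swapaxes(T, -1, -2)).max()
        scale = max(np.abs(T).max(), 1.0)
        if asym > atol * scale:
            raise ValueError("stress tensor is not symmetric")
    tr = np.trace(T, axis1=-2, axis2=-1)
    T_dev = T - tr[..., None, None] / 3.0 * _I3
    tau = np.sqrt(0.5 * np.einsum("...ij,...ij->...", T_dev, T_dev))
    # a deviator at round-off level has no meaningful direction
    floor = 1e-14 * np.maximum(np.abs(T).max(axis=(-2, -1)), 1.0)
    nonzero = tau > floor
    denom = np.where(nonzero, tau * np.sqrt(2.0), 1.0)
    N = np.where(nonzero[..., None, None], T_dev / denom[..., None, None], 0.0)
    return T_dev, tau, N


def _dev(A):
    tr = np.trace(A, axis1=-2, axis2=-1)
    return A - tr[..., None, None] / 3.0 * _I3


def _push_forward(F, S):
    """Cauchy stress from a second Piola–Kirchhoff stress: F S Fᵀ / det F."""
    J = np.linalg.det(F)
    return np.einsum("...ik,...kl,...jl->...ij", F, S, F) / J[..., None, None]


def green_lagrange(F):
    C = np.einsum("...ki,...kj->...ij", F, F)
    return 0.5 * (C - _I3)


# ----------------------------------------------------------------------
# state container
# ----------------------------------------------------------------------

@dataclass
class MaterialState:
    """Per-quadrature-point history.

    ``F`` is the last accepted total deformation gradient, ``F_vp`` the
    viscoplastic part (``F_ve = F · F_vp⁻¹``); ``branch_strain_1/2`` are
    the viscous deviatoric Green–Lagrange strains of the two Maxwell
    branches; ``D`` the scalar damage; ``kappa`` the accumulated plastic
    strain; ``t`` the elapsed time.
    """

    F: np.ndarray
    F_vp: np.ndarray
    branch_strain_1: np.ndarray
    branch_strain_2: np.ndarray
    D: np.ndarray
    kappa: np.ndarray
    t: float = 0.0

    @classmethod
    def pristine(cls, n: int | tuple = ()) -> "MaterialState":
        shape = (n,) if isinstance(n, int) else tuple(n)
        eye = np.broadcast_to(_I3, shape + (3, 3)).copy()
        zeros = np.zeros(shape + (3, 3))
        return cls(F=eye.copy(), F_vp=eye.copy(),
                   branch_strain_1=zeros.copy(), branch_strain_2=zeros.copy(),
                   D=np.zeros(shape), kappa=np.zeros(shape), t=0.0)

    @property
    def F_ve(self) -> np.ndarray:
        return self.F @ np.linalg.inv(self.F_vp)

    def copy(self) -> "MaterialState":
        return MaterialState(self.F.copy(), self.F_vp.copy(),
                             self.branch_strain_1.copy(), self.branch_strain_2.copy(),
                             self.D.copy(), self.kappa.copy(), self.t)


@dataclass
class StressResult:
    """Stress decomposition returned by a constitutive update (MPa).

    ``tangent_scale`` is the scalar return-map derivative d tau / d tau_trial
    per point (1 in the elastic domain); the FE solver uses it to soften
    its modified-Newton stiffness where plastic flow is active.
    """

    T: np.ndarray
    TE0: np.ndarray
    TE1: np.ndarray
    TE2: np.ndarray
    T_dev: np.ndarray
    tau: np.ndarray
    N: np.ndarray
    Y: np.ndarray
    tangent_scale: np.ndarray | float = 1.0


# ----------------------------------------------------------------------
# branch updates
# ----------------------------------------------------------------------

def equilibrium_branch_stress(state: MaterialState, bvtv, params: MaterialParameters
                              ) -> np.ndarray:
    """Cauchy stress of the equilibrium (fully elastic) branch.

    Saint-Venant response in the viscoelastic intermediate configuration:
    ``S = TF (1-D) (2 mu00 E' + k00 tr(E) I)`` pushed forward by F_ve.
    """
    p = params.mpa() if isinstance(params, MaterialParameters) else params
    F_ve = state.F_ve
    J = np.linalg.det(F_ve)
    if np.any(J <= 0):
        raise ConstitutiveError("det(F_ve) <= 0: corrupted state")
    tf = tissue_function(bvtv, p.Emax, p.E00, p.k_exp)
    mu0, k0 = elastic_moduli(p.E00, p.nu)
    E = green_lagrange(F_ve)
    scale = np.asarray(tf * (1.0 - state.D))[..., None, None]
    S = scale * (2.0 * mu0 * _dev(E)
                 + k0 * np.trace(E, axis1=-2, axis2=-1)[..., None, None] * _I3)
    return _push_forward(F_ve, S)


def viscoelastic_branch_update(branch_strain, dev_strain_old, dev_strain_new,
                               dt, eta_i, mu_i, stiffness_scale, viscosity_scale):
    """Advance one deviatoric Maxwell branch over a time step.

    The branch obeys ``eps'_dot = 3/(2 eta~) T + 3/(2 mu~) T_dot`` with
    ``mu~ = mu_i * stiffness_scale`` and ``eta~ = eta_i * viscosity_scale``;
    ``branch_strain`` is the viscous part of the deviatoric strain, and
    the branch stress is ``T = (2 mu~/3)(eps' - eps'_viscous)``.

    Integrated exactly for a constant strain rate over the step
    (exponential integrator): this matches the central-difference update
    to second order for ``dt`` below the branch time constant and stays
    stable and ringing-free in the stiff limit ``dt >> eta/mu`` that
    quasi-static loading produces.

    Returns ``(branch_strain', T')``.  Under held strain the branch
    stress relaxes exponentially with time constant ``eta_i / mu_i``
    (density scaling cancels).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mu_eff = mu_i * np.asarray(stiffness_scale, dtype=float)
    eta_eff = eta_i * np.asarray(viscosity_scale, dtype=float)
    if np.any(mu_eff <= 0) or np.any(eta_eff <= 0):
        raise ValueError("branch modulus and viscosity must be positive")
    g = (2.0 / 3.0) * mu_eff[..., None, None]
    x = dt * (mu_eff / eta_eff)[..., None, None]  # dt / time-constant
    decay = np.exp(-x)
    # (1 - e^-x)/x with a stable small-x limit
    ramp = np.where(x > 1e-10, -np.expm1(-x) / np.where(x > 1e-10, x, 1.0), 1.0)
    T_old = g * (dev_strain_old - branch_strain)
    T_new = decay * T_old + g * (dev_strain_new - dev_strain_old) * ramp
    ev_new = dev_strain_new - T_new / g
    return ev_new, T_new


# ----------------------------------------------------------------------
# plasticity and damage
# ----------------------------------------------------------------------

def plastic_stretch_rate(tau, N, S0, m):
    """Co-directional power-law flow: ``D_vp = (tau / (sqrt(3) S0))**m N``."""
    if np.any(np.asarray(S0) <= 0):
        raise ValueError("reference stress S0 must be positive")
    tau = np.asarray(tau, dtype=float)
    rate = (tau / (np.sqrt(3.0) * S0)) ** m
    return rate[..., None, None] * N if tau.ndim else rate * N


def _expm_small(A):
    """4th-order truncated matrix exponential (valid for small ||A||)."""
    A2 = A @ A
    A3 = A2 @ A
    A4 = A3 @ A
    return _I3 + A + A2 / 2.0 + A3 / 6.0 + A4 / 24.0


def update_plastic_gradient(F_ve, F_vp, F_total, D_vp, dt):
    """Integrate ``F_vp_dot = F_ve⁻¹ D_vp F`` by the exponential map.

    With ``F = F_ve F_vp`` this is ``F_vp_dot = L~ F_vp`` where
    ``L~ = F_ve⁻¹ D_vp F_ve``; a truncated exponential of ``dt L~``
    preserves ``det F_vp`` to high order for traceless flow.
    Returns ``(F_vp', d_kappa)`` with ``d_kappa = sqrt(2/3) ||D_vp|| dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    F_ve_inv = np.linalg.inv(F_ve)
    L = np.einsum("...ik,...kl,...lj->...ij", F_ve_inv, D_vp, F_ve)
    F_vp_new = _expm_small(dt * L) @ F_vp
    if np.any(np.linalg.det(F_vp_new) <= 0):
        raise ConstitutiveError("det(F_vp) <= 0 after plastic update; reduce the step")
    norm = np.sqrt(np.einsum("...ij,...ij->...", D_vp, D_vp))
    d_kappa = np.sqrt(2.0 / 3.0) * norm * dt
    return F_vp_new, d_kappa


def hill_tensor(params: MaterialParameters, tf_scale=1.0):
    """Halfspacewise Hill strength tensors in 6x6 Mandel form.

    Returns ``(F_plus, F_minus)`` for the tension / compression
    halfspaces.  Component order ``[11, 22, 33, sqrt2*23, sqrt2*13,
    sqrt2*12]``; the quadratic form ``s·F·s`` equals 1 for a uniaxial
    stress of magnitude ``sigma0`` or a pure shear of magnitude ``tau0``
    (isotropic fabric, eigenvalues 1).  Both tensors carry the
    ``1/TF**2`` leading factor.
    """
    p = params.mpa() if isinstance(params, MaterialParameters) else params
    tf_scale = float(tf_scale)
    if tf_scale <= 0:
        raise ValueError("tissue-function scale must be positive")

    def _one(sigma0, chi0):
        H = np.zeros((6, 6))
        H[:3, :3] = -chi0 / sigma0 ** 2
        np.fill_diagonal(H[:3, :3], 1.0 / sigma0 ** 2)
        for k in range(3, 6):
            H[k, k] = 1.0 / (2.0 * p.tau0 ** 2)
        return H / tf_scale ** 2

    return _one(p.sigma0_plus, p.chi0_plus), _one(p.sigma0_minus, p.chi0_minus)


def _hill_equivalent(S, params: MaterialParametersMPa, tf):
    """sqrt(S:F±:S), halfspace chosen by the sign of tr(S).  Vectorized."""
    trS = np.trace(S, axis1=-2, axis2=-1)
    d = np.einsum("...ii->...i", S)
    sum_d2 = np.einsum("...i,...i->...", d, d)
    s12, s13, s23 = S[..., 0, 1], S[..., 0, 2], S[..., 1, 2]
    shear = (s12 ** 2 + s13 ** 2 + s23 ** 2) / params.tau0 ** 2
    cross = trS ** 2 - sum_d2

    def _q(sigma0, chi0):
        return (sum_d2 - chi0 * cross) / sigma0 ** 2 + shear

    q_plus = _q(params.sigma0_plus, params.chi0_plus)
    q_minus = _q(params.sigma0_minus, params.chi0_minus)
    q = np.where(trS > 0, q_plus, q_minus)
    q = np.clip(q, 0.0, None) / np.asarray(tf, dtype=float) ** 2
    return np.sqrt(q)


def corotate(F, T):
    """Pull a spatial tensor back through the rotation of F's polar
    decomposition (R from F = R U): returns Rᵀ T R.

    The Hill criterion is anchored to the material fabric axes; under a
    superposed rigid rotation the Cauchy stress rotates while the fabric
    tensors do not, so frame indifference requires evaluating the
    criterion on the corotated stress.
    """
    U, _s, Vt = np.linalg.svd(F)
    R = U @ Vt
    return np.einsum("...ji,...jk,...kl->...il", R, T, R)


def damage_hardening(D, alpha, k_hard):
    """Yield-surface radius ``r(D) = 1 - (1 - alpha) exp(-k_hard D)``."""
    return 1.0 - (1.0 - alpha) * np.exp(-k_hard * np.asarray(D, dtype=float))


def yield_value(S, params: MaterialParameters, D, tf=1.0):
    """Hill yield function ``Y = sqrt(S_eff:F±:S_eff) - r(D)`` (Y < 0: elastic).

    The criterion lives in effective-stress space: the nominal stress is
    divided by ``(1 - D)`` before entering the quadratic form, so the
    yield surface (which hardens through ``r(D)``) is not artificially
    shut by the very stiffness degradation that damage causes.
    """
    p = params.mpa() if isinstance(params, MaterialParameters) else params
    seq = _hill_equivalent(np.asarray(S, dtype=float), p, tf)
    seq_eff = seq / np.maximum(1.0 - np.asarray(D, dtype=float), 1e-6)
    return seq_eff - damage_hardening(D, p.alpha, p.k_hard)


def update_damage(D, kappa, d_kappa, zeta):
    """Saturating damage law ``D = 1 - exp(-zeta * kappa)``, never decreasing."""
    d_kappa = np.asarray(d_kappa, dtype=float)
    if np.any(d_kappa < 0):
        raise ValueError("plastic-strain increment must be non-negative")
    kappa_new = kappa + d_kappa
    D_new = np.maximum(D, 1.0 - np.exp(-zeta * kappa_new))
    return np.clip(D_new, 0.0, 1.0), kappa_new


# ----------------------------------------------------------------------
# full material-point step
# ----------------------------------------------------------------------

def _stresses(F, F_vp, ev1_old, ev2_old, E_dev_old, D, tf,
              p: MaterialParametersMPa, dt):
    """Stress evaluation at fixed internal variables (one CN branch pass)."""
    F_ve = F @ np.linalg.inv(F_vp)
    J_ve = np.linalg.det(F_ve)
    if np.any(J_ve <= 0):
        raise ConstitutiveError("det(F_ve) <= 0 during update")
    E = green_lagrange(F_ve)
    E_dev = _dev(E)
    trE = np.trace(E, axis1=-2, axis2=-1)

    stiff = tf * (1.0 - D)
    mu0, k0 = elastic_moduli(p.E00, p.nu)
    S0pk = stiff[..., None, None] * (2.0 * mu0 * E_dev
                                     + k0 * trE[..., None, None] * _I3)

    mu1, _ = elastic_moduli(p.E01, p.nu)
    mu2, _ = elastic_moduli(p.E02, p.nu)
    ev1_new, S1 = viscoelastic_branch_update(
        ev1_old, E_dev_old, E_dev, dt, p.eta01, mu1, stiff, tf)
    ev2_new, S2 = viscoelastic_branch_update(
        ev2_old, E_dev_old, E_dev, dt, p.eta02, mu2, stiff, tf)

    TE0 = _push_forward(F_ve, S0pk)
    TE1 = _push_forward(F_ve, S1)
    TE2 = _push_forward(F_ve, S2)
    T = TE0 + TE1 + TE2
    return F_ve, E_dev, ev1_new, ev2_new, TE0, TE1, TE2, T, stiff


def _solve_return(tau_trial, mu_corr, dt, s0_eff, m):
    """Implicit scalar return: find tau_n solving
    ``tau_trial = tau_n + sqrt(2) mu_corr dt (tau_n / (sqrt(3) s0_eff))**m``
    by vectorized bisection (monotone, unique root in [0, tau_trial])."""
    lo = np.zeros_like(tau_trial)
    hi = tau_trial.copy()
    a = np.sqrt(3.0) * s0_eff
    c = np.sqrt(2.0) * mu_corr * dt
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        f = tau_trial - mid - c * (mid / a) ** m
        lo = np.where(f > 0, mid, lo)
        hi = np.where(f > 0, hi, mid)
    return 0.5 * (lo + hi)


def material_point_update(F_new, dt, state: MaterialState, bvtv,
                          params: MaterialParameters):
    """One full constitutive step; returns ``(StressResult, MaterialState)``.

    Elastic–viscoelastic predictor (Crank–Nicolson Maxwell branches),
    Hill yield check on the trial Cauchy stress, implicit scalar
    viscoplastic return along the deviatoric direction, exponential-map
    update of ``F_vp``, plasticity-coupled damage update, and a
    corrector stress pass at the updated internal state.  Sub-steps
    automatically when the plastic increment is large.
    """
    p = params.mpa() if isinstance(params, MaterialParameters) else params
    F_new = np.asarray(F_new, dtype=float)
    if np.any(np.linalg.det(F_new) <= 0):
        raise ConstitutiveError("det(F) <= 0 in imposed deformation gradient")
    if dt <= 0:
        raise ValueError("dt must be positive")

    tf = np.asarray(tissue_function(bvtv, p.Emax, p.E00, p.k_exp), dtype=float)
    s0_eff = p.S0 * tf

    F_old = state.F

    # optimistic single step; redo with sub-steps when the plastic
    # increment is too large for the explicit flow direction.  Points
    # that are already essentially fully damaged carry near-zero stress
    # and are excluded from the refinement criterion.
    alive = np.asarray(state.D) < _D_DEAD
    n_sub = 1
    while True:
        st = state.copy()
        try:
            result = None
            for k in range(1, n_sub + 1):
                F_k = F_old + (k / n_sub) * (F_new - F_old)
                result, st = _single_step(F_k, dt / n_sub, st, tf, s0_eff, p)
            dk = np.where(alive, st.kappa - state.kappa, 0.0)
            dgamma = float(np.max(dk)) / np.sqrt(2.0 / 3.0)
            if dgamma <= _DGAMMA_MAX * n_sub or n_sub >= _MAX_SUBSTEPS:
                return result, st
            n_sub = int(min(max(2 * n_sub, np.ceil(dgamma / _DGAMMA_MAX)),
                            _MAX_SUBSTEPS))
        except ConstitutiveError:
            if n_sub >= _MAX_SUBSTEPS:
                raise
            n_sub = min(4 * n_sub, _MAX_SUBSTEPS)


def _single_step(F_new, dt, st: MaterialState, tf, s0_eff,
                 p: MaterialParametersMPa):
    E_dev_old = _dev(green_lagrange(st.F_ve))

    # --- predictor: frozen F_vp, frozen damage -------------------------
    (F_ve, E_dev, ev1_new, ev2_new, TE0, TE1, TE2, T, _stiff) = _stresses(
        F_new, st.F_vp, st.branch_strain_1, st.branch_strain_2,
        E_dev_old, st.D, tf, p, dt)
    T_dev, tau, N = deviatoric_split(T, check_symmetry=False)
    seq = _hill_equivalent(corotate(F_ve, T), p, tf) \
        / np.maximum(1.0 - st.D, 1e-6)
    Y = seq - damage_hardening(st.D, p.alpha, p.k_hard)

    plastic = (Y >= 0.0) & (tau > 0.0)
    tangent_scale = np.ones_like(np.asarray(tau, dtype=float))
    any_plastic = bool(np.any(plastic))
    if any_plastic:
        mu0, _ = elastic_moduli(p.E00, p.nu)
        if tangent_scale.ndim == 0:
            # effective-stress concept: damage degrades the flow stress
            # along with the stiffness, so the material genuinely softens
            s0_loc = s0_eff * np.maximum(1.0 - st.D, 1e-6)
            mu_corr = mu0 * tf * (1.0 - st.D)
            tau_n = _solve_return(np.where(plastic, tau, 0.0), mu_corr, dt,
                                  s0_loc, p.m)
            gamma_dot = np.where(plastic,
                                 (tau_n / (np.sqrt(3.0) * s0_loc)) ** p.m, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                phi = 1.0 / (1.0 + np.sqrt(2.0) * mu_corr * dt * p.m * gamma_dot
                             / np.maximum(tau_n, 1e-30))
            tangent_scale = np.where(plastic, phi, 1.0)
            D_vp = gamma_dot[..., None, None] * N
            F_vp_new, d_kappa = update_plastic_gradient(F_ve, st.F_vp, F_new,
                                                        D_vp, dt)
        else:  # operate on the plastic subset only (usually small)
            idx = np.nonzero(plastic.reshape(-1))[0]
            shp = plastic.shape
            tf_b = np.broadcast_to(tf, shp).reshape(-1)[idx]
            D_b = st.D.reshape(-1)[idx]
            s0_b = np.broadcast_to(s0_eff, shp).reshape(-1)[idx] \
                * np.maximum(1.0 - D_b, 1e-6)
            tau_b = tau.reshape(-1)[idx]
            mu_corr = mu0 * tf_b * (1.0 - D_b)
            tau_n = _solve_return(tau_b, mu_corr, dt, s0_b, p.m)
            gamma_dot = (tau_n / (np.sqrt(3.0) * s0_b)) ** p.m
            with np.errstate(divide="ignore", invalid="ignore"):
                phi = 1.0 / (1.0 + np.sqrt(2.0) * mu_corr * dt * p.m * gamma_dot
                             / np.maximum(tau_n, 1e-30))
            tangent_scale.reshape(-1)[idx] = phi
            D_vp = gamma_dot[:, None, None] * N.reshape(-1, 3, 3)[idx]
            F_vp_sub, dk_sub = update_plastic_gradient(
                F_ve.reshape(-1, 3, 3)[idx], st.F_vp.reshape(-1, 3, 3)[idx],
                F_new.reshape(-1, 3, 3)[idx], D_vp, dt)
            F_vp_new = st.F_vp.copy()
            F_vp_new.reshape(-1, 3, 3)[idx] = F_vp_sub
            d_kappa = np.zeros(shp)
            d_kappa.reshape(-1)[idx] = dk_sub
        D_new, kappa_new = update_damage(st.D, st.kappa, d_kappa, p.zeta)
        # corrector: stresses at the updated internal state
        (F_ve, E_dev, ev1_new, ev2_new, TE0, TE1, TE2, T, _stiff) = _stresses(
            F_new, F_vp_new, st.branch_strain_1, st.branch_strain_2,
            E_dev_old, D_new, tf, p, dt)
        T_dev, tau, N = deviatoric_split(T, check_symmetry=False)
        Y = _hill_equivalent(corotate(F_ve, T), p, tf) \
            / np.maximum(1.0 - D_new, 1e-6) \
            - damage_hardening(D_new, p.alpha, p.k_hard)
    else:
        F_vp_new, D_new, kappa_new = st.F_vp, st.D, st.kappa

    new_state = MaterialState(F=F_new.copy(), F_vp=F_vp_new,
                              branch_strain_1=ev1_new, branch_strain_2=ev2_new,
                              D=D_new, kappa=kappa_new, t=st.t + dt)
    res = StressResult(T=T, TE0=TE0, TE1=TE1, TE2=TE2,
                       T_dev=T_dev, tau=tau, N=N, Y=Y,
                       tangent_scale=tangent_scale)
    return res, new_state


# ----------------------------------------------------------------------
# scripted strain-path driver
# ----------------------------------------------------------------------

def run_strain_path(times, F_path, bvtv, params: MaterialParameters,
                    state: MaterialState | None = None):
    """Drive a single material point through a deformation-gradient history.

    ``times``: increasing array (s), ``F_path``: (n, 3, 3).  Returns the
    list of :class:`StressResult` and the final state.  The initial
    entry must be close to the current state's gradient.
    """
    times = np.asarray(times, dtype=float)
    F_path = np.asarray(F_path, dtype=float)
    if state is None:
        state = MaterialState.pristine(())
    results = []
    for i in range(1, len(times)):
        dt = times[i] - times[i - 1]
        res, state = material_point_update(F_path[i], dt, state, bvtv, params)
        results.append(res)
    return results, state


def load_strain_path_csv(path):
    """Read a (time, F11..F33) CSV driver file → (times, F_path)."""
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    times = data[:, 0]
    F_path = data[:, 1:10].reshape(-1, 3, 3)
    return times, F_path
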