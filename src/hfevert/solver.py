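"""Quasi-static displacement-controlled FE compression of a vertebral mesh.

The boundary-value problem mirrors a plane-parallel vertebral-section
compression test: a monotonically increasing craniocaudal displacement
imposed on the cranial surface, an encastre (fully clamped) condition on
the caudal surface, and the reaction force taken as the sum of the
internal-force residuals over the cranial nodes.  The run terminates
when any quadrature point is fully damaged or the displacement protocol
is exhausted.

Discretization: linear tetrahedra with a single quadrature point,
total-Lagrangian internal force (``f = V0 · P · ∇N`` with
``P = J σ F⁻ᵀ``), and a modified Newton iteration whose stiffness is a
per-element isotropic secant (tissue-function-, damage- and
plasticity-scaled).  Convergence is measured on the residual, so the
equilibrium path is not affected by the tangent approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as cm
from .experiment import LoadDisplacementCurve, extract_stiffness, extract_strength
from .mesh import TetMesh
from .parameters import MaterialParameters

NEWTON_RTOL = 1e-5
NEWTON_MAX_ITER = 25
#: iterations without a new best residual before abandoning an increment
NEWTON_STALL = 8
MAX_HALVINGS = 5
DAMAGE_STOP = 1.0 - 1e-9


class SolverError(RuntimeError):
    pass


@dataclass
class LoadProtocol:
    """Compression protocol: rate in mm/min (test-machine convention).

    ``damage_stop`` is the local-damage level treated as complete
    failure of a quadrature point; the default demands D within 1e-9 of
    1, which the saturating damage law approaches only asymptotically —
    lower it to terminate runs at a chosen damage severity.
    """

    max_displacement: float
    displacement_rate: float = 5.0
    increment: float | None = None
    direction: tuple = (0.0, 0.0, -1.0)
    damage_stop: float = DAMAGE_STOP

    def __post_init__(self):
        if self.displacement_rate <= 0 or self.max_displacement <= 0:
            raise ValueError("rate and max displacement must be positive")
        if self.increment is None:
            self.increment = self.max_displacement / 100.0
        if not (0 < self.increment <= self.max_displacement):
            raise ValueError("increment must lie in (0, max_displacement]")

    @property
    def rate_mm_s(self) -> float:
        return self.displacement_rate / 60.0


@dataclass
class SimulationResult:
    curve: LoadDisplacementCurve
    von_mises: list = field(default_factory=list)
    damage: list = field(default_factory=list)
    stop_reason: str = "max_displacement"
    strength_kN: float = np.nan
    stiffness_kN_per_mm: float = np.nan
    increments: list = field(default_factory=list)

    def save_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as fh:
            fh.create_dataset("displacement_mm", data=self.curve.displacement)
            fh.create_dataset("force_kN", data=self.curve.force)
            fh.create_dataset("von_mises_MPa", data=np.asarray(self.von_mises))
            fh.create_dataset("damage", data=np.asarray(self.damage))
            fh.attrs["stop_reason"] = self.stop_reason
            fh.attrs["strength_kN"] = self.strength_kN
            fh.attrs["stiffness_kN_per_mm"] = self.stiffness_kN_per_mm


# ----------------------------------------------------------------------
# element kinematics
# ----------------------------------------------------------------------

def element_operators(mesh: TetMesh):
    """Shape-function gradients (n_el, 4, 3) and volumes for tet4 elements."""
    X = mesh.nodes[mesh.elements]
    D = np.transpose(X[:, 1:] - X[:, :1], (0, 2, 1))  # columns X_i - X_0
    vols = np.linalg.det(D) / 6.0
    if np.any(vols <= 0):
        bad = int(np.argmin(vols))
        raise SolverError(f"non-positive volume in element {bad}")
    Dinv = np.linalg.inv(D)          # rows are grad N_i (i = 1..3)
    grads = np.empty((len(X), 4, 3))
    grads[:, 1:, :] = Dinv
    grads[:, 0, :] = -Dinv.sum(axis=1)
    return grads, vols


def deformation_gradients(u_e: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """F = I + Σ_a u_a ⊗ ∇N_a per element."""
    return np.eye(3) + np.einsum("eai,eaj->eij", u_e, grads)


def assemble_internal_force(mesh: TetMesh, u: np.ndarray, states, params,
                            dt: float, grads=None, vols=None):
    """Internal nodal forces from per-element Cauchy stress.

    Returns ``(residual (n_nodes, 3), StressResult, trial_states)``; the
    trial states are not committed — the caller accepts them only when
    the increment converges.
    """
    if grads is None or vols is None:
        grads, vols = element_operators(mesh)
    if not np.all(np.isfinite(u)):
        raise SolverError("non-finite displacement field")
    u_e = u[mesh.elements]
    F = deformation_gradients(u_e, grads)
    res, trial = cm.material_point_update(F, dt, states, mesh.element_bvtv, params)
    J = np.linalg.det(F)
    Finv = np.linalg.inv(F)
    P = J[:, None, None] * np.einsum("eij,ekj->eik", res.T, Finv)  # J σ F^{-T}
    f_e = vols[:, None, None] * np.einsum("eij,eaj->eai", P, grads)
    R = np.zeros_like(u)
    np.add.at(R, mesh.elements.reshape(-1),
              f_e.reshape(-1, 3))
    return R, res, trial


# ----------------------------------------------------------------------
# tangent assembly
# ----------------------------------------------------------------------

def _voigt_C(nu: float) -> np.ndarray:
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[0, 0] = C[1, 1] = C[2, 2] = lam + 2 * mu
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def _element_B(grads: np.ndarray) -> np.ndarray:
    n = len(grads)
    B = np.zeros((n, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        B[:, 0, 3 * a + 0] = gx
        B[:, 1, 3 * a + 1] = gy
        B[:, 2, 3 * a + 2] = gz
        B[:, 3, 3 * a + 1] = gz
        B[:, 3, 3 * a + 2] = gy
        B[:, 4, 3 * a + 0] = gz
        B[:, 4, 3 * a + 2] = gx
        B[:, 5, 3 * a + 0] = gy
        B[:, 5, 3 * a + 1] = gx
    return B


class _Tangent:
    """Precomputed sparse pattern + fast per-iteration reassembly."""

    def __init__(self, mesh: TetMesh, params: MaterialParameters):
        self.grads, self.vols = element_operators(mesh)
        self.B = _element_B(self.grads)
        p = params.mpa()
        self.C_unit = _voigt_C(p.nu)
        self.E00 = p.E00
        self.p = p
        dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 12)
        self.rows = np.repeat(dofs, 12, axis=1).reshape(-1)
        self.cols = np.tile(dofs, (1, 12)).reshape(-1)
        self.ndof = 3 * mesh.n_nodes
        self.tf = cm.tissue_function(mesh.element_bvtv, p.Emax, p.E00, p.k_exp)
        self.K0 = np.einsum("eki,kl,elj->eij", self.B, self.C_unit, self.B) \
            * self.vols[:, None, None]

    def matrix(self, damage, tangent_scale) -> sp.csr_matrix:
        E_el = self.E00 * self.tf * (1.0 - damage) * tangent_scale
        E_el = np.maximum(E_el, 1e-6 * self.E00 * np.min(self.tf))
        data = (self.K0 * E_el[:, None, None]).reshape(-1)
        K = sp.coo_matrix((data, (self.rows, self.cols)),
                          shape=(self.ndof, self.ndof))
        return K.tocsr()


# ----------------------------------------------------------------------
# quasi-static solution
# ----------------------------------------------------------------------

def solve_quasi_static(mesh: TetMesh, params: MaterialParameters,
                       protocol: LoadProtocol, cranial_inplane: str = "free",
                       record_fields: bool = True, verbose: bool = False
                       ) -> SimulationResult:
    """Displacement-controlled quasi-static compression of a mesh.

    ``cranial_inplane``: 'free' leaves the in-plane dof of cranial nodes
    unconstrained (ball-joint-like loading platen); 'clamped' fixes them.
    """
    if mesh.element_bvtv is None:
        raise SolverError("mesh has no element BV/TV assigned")
    if len(mesh.cranial_nodes) == 0 or len(mesh.caudal_nodes) == 0:
        raise SolverError("mesh must have non-empty cranial and caudal node sets")
    mesh.validate()

    n = mesh.n_nodes
    ndof = 3 * n
    fixed = np.zeros(ndof, dtype=bool)
    for node in mesh.caudal_nodes:
        fixed[3 * node:3 * node + 3] = True
    cz = 3 * mesh.cranial_nodes + 2
    fixed[cz] = True
    if cranial_inplane == "clamped":
        fixed[3 * mesh.cranial_nodes] = True
        fixed[3 * mesh.cranial_nodes + 1] = True
    elif cranial_inplane != "free":
        raise ValueError("cranial_inplane must be 'free' or 'clamped'")
    free = ~fixed

    tangent = _Tangent(mesh, params)
    grads, vols = tangent.grads, tangent.vols
    states = cm.MaterialState.pristine(mesh.n_elements)

    u = np.zeros((n, 3))
    delta = 0.0
    inc = protocol.increment
    base_inc = inc
    disp_hist, force_hist = [0.0], [0.0]
    vm_hist, dmg_hist = [], []
    increments_log = []
    stop_reason = "max_displacement"
    halvings = 0
    successes = 0

    while delta < protocol.max_displacement - 1e-12:
        inc = min(inc, protocol.max_displacement - delta)
        dt = inc / protocol.rate_mm_s
        target = delta + inc
        u_trial = u.copy()
        u_trial.reshape(-1)[cz] = -target
        converged = False
        res = trial = None
        lu = None
        du_prev = None
        omega = 1.0
        damp = 1.0
        rnorm_prev = np.inf
        best_rnorm, best_it = np.inf, 0
        for it in range(NEWTON_MAX_ITER):
            R, res, trial = assemble_internal_force(
                mesh, u_trial, states, params, dt, grads, vols)
            Rflat = R.reshape(-1)
            reaction_scale = np.abs(Rflat[fixed]).max() if fixed.any() else 1.0
            tol = NEWTON_RTOL * max(reaction_scale, 1e-8)
            rnorm = np.abs(Rflat[free]).max() if free.any() else 0.0
            if verbose:
                print(f"  inc d={target:.4f} it={it} |R|={rnorm:.3e} tol={tol:.3e}")
            if rnorm <= tol:
                converged = True
                break
            if rnorm < 0.8 * best_rnorm:
                best_rnorm, best_it = rnorm, it
            elif it - best_it >= NEWTON_STALL:
                break  # stalled: no equilibrium in reach at this increment
            # refresh the (approximate) stiffness occasionally; the
            # residual check above is what controls accuracy
            if lu is None or it in (1, 3, 6, 10, 15, 21):
                K = tangent.matrix(trial.D, res.tangent_scale)
                lu = spla.splu(K[free][:, free].tocsc())
                du_prev, omega = None, 1.0
            du = lu.solve(-Rflat[free])
            # Aitken relaxation accelerates the linearly convergent
            # modified-Newton fixed point (essential once damage softens
            # the true tangent well below the secant stiffness); a
            # residual-watchdog damping suppresses flip-flopping between
            # plastic/elastic trial sets near the force peak
            if rnorm > rnorm_prev:
                damp = max(0.25 * damp, 0.05)
                omega, du_prev = 1.0, None
            else:
                damp = min(1.25 * damp, 1.0)
            if du_prev is not None:
                diff = du - du_prev
                denom = diff @ diff
                if denom > 0:
                    omega = float(np.clip(-omega * (du_prev @ diff) / denom,
                                          0.2, 4.0))
            u_trial.reshape(-1)[free] += damp * omega * du
            du_prev = du
            rnorm_prev = rnorm
        if not converged:
            # under displacement control a vanishing increment with no
            # equilibrium means structural failure (snap-back): stop and
            # report the partial curve
            halvings += 1
            successes = 0
            if halvings > MAX_HALVINGS or inc <= base_inc / 2 ** MAX_HALVINGS:
                stop_reason = "non_convergence"
                break
            inc *= 0.5
            continue

        # accept increment
        u = u_trial
        states = trial
        delta = target
        force_kN = -R.reshape(-1)[cz].sum() / 1000.0
        caudal_kN = -R[mesh.caudal_nodes, 2].sum() / 1000.0
        disp_hist.append(delta)
        force_hist.append(force_kN)
        increments_log.append({"displacement": delta, "force_kN": force_kN,
                               "caudal_force_kN": caudal_kN,
                               "iterations": it + 1, "max_D": float(states.D.max())})
        if record_fields:
            vm_hist.append(von_mises_field(res.T))
            dmg_hist.append(states.D.copy())
        if states.D.max() >= protocol.damage_stop:
            stop_reason = "damage_saturation"
            break
        # grow the increment back only after a run of clean successes,
        # otherwise the solver thrashes around the force peak
        successes += 1
        if halvings == 0 and inc < base_inc and successes >= 3:
            inc = min(2 * inc, base_inc)
            successes = 0
        halvings = 0

    curve = LoadDisplacementCurve(np.asarray(disp_hist), np.asarray(force_hist))
    result = SimulationResult(curve=curve, von_mises=vm_hist, damage=dmg_hist,
                              stop_reason=stop_reason, increments=increments_log)
    try:
        result.strength_kN = extract_strength(curve)
        result.stiffness_kN_per_mm = extract_stiffness(curve)
    except ValueError:
        pass
    return result


def von_mises_field(T: np.ndarray) -> np.ndarray:
    """Per-element von Mises equivalent stress sqrt(3/2 T':T') (MPa)."""
    tr = np.trace(T, axis1=-2, axis2=-1)
    Td = T - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", Td, Td))


def export_vtk_series(mesh: TetMesh, result: SimulationResult, out_dir) -> None:
    """Per-increment VTK files with von Mises stress and damage."""
    import pathlib

    from .mesh import write_vtk
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, (vm, dm) in enumerate(zip(result.von_mises, result.damage)):
        write_vtk(mesh, out / f"step_{k:04d}.vtk",
                  cell_data={"von_mises": vm, "damage": dm})
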