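"""Material-parameter calibration.

Two modes, mirroring how homogenized vertebral FE models are fitted to
compression experiments:

* *specimen-specific*: iterative proportional adjustment of two scale
  factors — ``s_E`` multiplying the elastic family (all branch moduli,
  plus the branch viscosities with an extra fixed 1/100 to suppress
  rate effects in quasi-static runs) and ``s_S`` multiplying the
  strength family — until the simulated load–displacement curve matches
  the reference within a normalized RMSE tolerance (default 5 %).
* *global*: one parameter set across specimens, found by Latin-hypercube
  sampling of the scale box, a small feed-forward surrogate network
  (hidden layers 20 and 10) trained on (scales → objective) pairs, and
  gradient descent on the surrogate, with the proposal re-scored by the
  true objective.

The objective combines the root-mean-square and the spread of the
per-specimen normalized curve errors: ``Obj = λ·RMS(e) + (1-λ)·SD(e)``
with λ = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc
from sklearn.neural_network import MLPRegressor

from .experiment import (LoadDisplacementCurve, curve_rmse, extract_stiffness,
                         extract_strength, normalized_error)
from .parameters import MaterialParameters

#: fixed extra reduction of branch viscosities during calibration
VISCOSITY_REDUCTION = 1.0 / 100.0


@dataclass(frozen=True)
class CalibrationScales:
    """Proportional parameter families.

    ``s_E`` scales E00, E01, E02 jointly (and eta01, eta02 with the
    extra 1/100); ``s_S`` scales the strength family sigma0±, tau0 and
    the viscoplastic reference stress S0.  Dimensionless constants
    (m, chi0±, alpha, zeta, k_exp) are held fixed.
    """

    s_E: float = 1.0
    s_S: float = 1.0

    def __post_init__(self):
        if self.s_E <= 0 or self.s_S <= 0:
            raise ValueError("scales must be positive")


def apply_scales(base: MaterialParameters, scales: CalibrationScales
                 ) -> MaterialParameters:
    """Scaled parameter set (viscosities always carry the 1/100 factor)."""
    return base.replace(
        E00=base.E00 * scales.s_E,
        E01=base.E01 * scales.s_E,
        E02=base.E02 * scales.s_E,
        eta01=base.eta01 * scales.s_E * VISCOSITY_REDUCTION,
        eta02=base.eta02 * scales.s_E * VISCOSITY_REDUCTION,
        Emax=base.Emax * scales.s_E,
        sigma0_minus=base.sigma0_minus * scales.s_S,
        sigma0_plus=base.sigma0_plus * scales.s_S,
        tau0=base.tau0 * scales.s_S,
        S0=base.S0 * scales.s_S,
    )


@dataclass
class CalibrationResult:
    scales: CalibrationScales
    params: MaterialParameters
    rmse: float
    converged: bool
    trace: list = field(default_factory=list)


def specimen_calibrate(forward_model, ref_curve: LoadDisplacementCurve,
                       base: MaterialParameters, tol: float = 5.0,
                       max_iter: int = 50) -> CalibrationResult:
    """Iterative proportional calibration against a reference curve.

    ``forward_model(params) -> LoadDisplacementCurve`` is the simulator
    on a fixed mesh.  Stiffness mismatch drives ``s_E``, strength
    mismatch drives ``s_S``; the multiplicative step is damped when an
    update fails to improve the RMSE.  Stops at RMSE <= ``tol`` (percent
    of reference peak force) or after ``max_iter`` forward evaluations.
    """
    k_ref = extract_stiffness(ref_curve)
    f_ref = extract_strength(ref_curve)
    scales = CalibrationScales()
    best = None
    step = 1.0
    trace = []
    for it in range(max_iter):
        params = apply_scales(base, scales)
        curve = forward_model(params)
        rmse = curve_rmse(curve, ref_curve)
        k_sim = extract_stiffness(curve)
        f_sim = extract_strength(curve)
        trace.append({"iteration": it, "s_E": scales.s_E, "s_S": scales.s_S,
                      "rmse": rmse, "stiffness": k_sim, "strength": f_sim})
        if best is None or rmse < best[1]:
            best = (scales, rmse)
        else:
            # overshoot: damp the step and restart from the best point
            step *= 0.5
            scales = best[0]
        if rmse <= tol:
            return CalibrationResult(scales, params, rmse, True, trace)
        ratio_E = np.clip(k_ref / max(k_sim, 1e-12), 0.2, 5.0)
        ratio_S = np.clip(f_ref / max(f_sim, 1e-12), 0.2, 5.0)
        scales = CalibrationScales(s_E=scales.s_E * ratio_E ** step,
                                   s_S=scales.s_S * ratio_S ** step)
    scales, rmse = best
    return CalibrationResult(scales, apply_scales(base, scales), rmse, False, trace)


# ----------------------------------------------------------------------
# global objective and surrogate optimization
# ----------------------------------------------------------------------

def objective(errors, lam: float = 0.5) -> float:
    """``Obj = λ·RMS(e) + (1-λ)·SD(e)`` over per-specimen errors."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one error value")
    rms = float(np.sqrt(np.mean(e ** 2)))
    sd = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    return lam * rms + (1.0 - lam) * sd


class Surrogate:
    """Feed-forward surrogate of the calibration objective.

    Standardized inputs/outputs around an MLP with hidden layers
    (20, 10); deterministic for a fixed seed.  Gradients with respect to
    the *inputs* are taken by central finite differences — the surrogate
    is smooth and cheap, so this is both robust and exact enough for
    the outer gradient descent.
    """

    def __init__(self, net, x_mean, x_std, y_mean, y_std, val_loss):
        self._net = net
        self._xm, self._xs = x_mean, x_std
        self._ym, self._ys = y_mean, y_std
        self.validation_loss = val_loss

    def __call__(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self._xm) / self._xs
        y = self._net.predict(z) * self._ys + self._ym
        return y if len(y) > 1 else float(y[0])

    def gradient(self, x, h: float = 1e-4):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for i in range(len(x)):
            dp = x.copy(); dp[i] += h
            dm = x.copy(); dm[i] -= h
            g[i] = (self(dp) - self(dm)) / (2 * h)
        return g


def train_surrogate(samples, values, seed: int = 0, hidden=(20, 10),
                    val_fraction: float = 0.2) -> Surrogate:
    """Train the surrogate network on (parameter vector, objective) pairs."""
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    y = np.asarray(values, dtype=float)
    if len(X) < 20:
        raise ValueError("need at least 20 samples to train the surrogate")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("samples and objective values must be finite")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    n_val = max(1, int(round(val_fraction * len(X))))
    val, tr = perm[:n_val], perm[n_val:]
    xm, xs = X[tr].mean(axis=0), X[tr].std(axis=0) + 1e-12
    ym, ys = y[tr].mean(), y[tr].std() + 1e-12
    net = MLPRegressor(hidden_layer_sizes=tuple(hidden), activation="tanh",
                       solver="lbfgs", max_iter=20000, tol=1e-12,
                       random_state=int(seed) % (2 ** 31))
    net.fit((X[tr] - xm) / xs, (y[tr] - ym) / ys)
    pred_val = net.predict((X[val] - xm) / xs) * ys + ym
    val_loss = float(np.mean((pred_val - y[val]) ** 2))
    if not np.isfinite(val_loss):
        raise RuntimeError(f"surrogate training diverged (loss trace: {net.loss_})")
    return Surrogate(net, xm, xs, ym, ys, val_loss)


@dataclass
class GlobalCalibrationResult:
    scales: CalibrationScales
    params: MaterialParameters
    objective: float
    per_specimen_errors: list
    exhausted: bool
    surrogate: Surrogate | None = None
    samples: np.ndarray | None = None
    sample_objectives: np.ndarray | None = None


def _true_objective(x, specimens, base, lam):
    scales = CalibrationScales(s_E=float(x[0]), s_S=float(x[1]))
    params = apply_scales(base, scales)
    errors = [normalized_error(forward(params), ref) for forward, ref in specimens]
    return objective(errors, lam), errors


def global_optimize(specimens, base: MaterialParameters, budget: int = 200,
                    seed: int = 0, bounds=None, lam: float = 0.5,
                    descent_steps: int = 200, restarts: int = 3
                    ) -> GlobalCalibrationResult:
    """Single parameter set across specimens via surrogate optimization.

    ``specimens``: list of ``(forward_model, reference_curve)`` pairs.
    ``bounds``: [(lo, hi)] per scale; typically the range spanned by the
    per-specimen calibrations.  ``budget`` counts true-objective
    evaluations used to seed the surrogate.
    """
    if len(specimens) == 0:
        raise ValueError("need at least one specimen")
    if bounds is None:
        bounds = [(0.5, 2.0), (0.5, 2.0)]
    bounds = np.asarray(bounds, dtype=float)
    d = len(bounds)

    sampler = qmc.LatinHypercube(d=d, seed=int(seed) % (2 ** 31))
    unit = sampler.random(n=budget)
    X = qmc.scale(unit, bounds[:, 0], bounds[:, 1])
    evals = []
    errs = []
    for x in X:
        obj, e = _true_objective(x, specimens, base, lam)
        evals.append(obj)
        errs.append(e)
    evals = np.asarray(evals)

    sur = train_surrogate(X, evals, seed=seed)

    # gradient descent on the surrogate from the best samples
    order = np.argsort(evals)
    starts = [X[order[k % len(X)]] for k in range(restarts)]
    candidates = []
    for x0 in starts:
        x = x0.copy()
        lr = 0.05 * (bounds[:, 1] - bounds[:, 0])
        for _ in range(descent_steps):
            g = sur.gradient(x)
            x_new = np.clip(x - lr * g, bounds[:, 0], bounds[:, 1])
            if sur(x_new) > sur(x):
                lr *= 0.5
                if np.max(lr) < 1e-6:
                    break
            else:
                x = x_new
        candidates.append(x)

    best_i = int(np.argmin(evals))
    best_x, best_obj, best_errs = X[best_i], float(evals[best_i]), errs[best_i]
    exhausted = True
    for x in candidates:
        obj, e = _true_objective(x, specimens, base, lam)
        if obj < best_obj:
            best_x, best_obj, best_errs = x, obj, e
            exhausted = False
    scales = CalibrationScales(s_E=float(best_x[0]), s_S=float(best_x[1]))
    return GlobalCalibrationResult(
        scales=scales, params=apply_scales(base, scales), objective=best_obj,
        per_specimen_errors=best_errs, exhausted=exhausted, surrogate=sur,
        samples=X, sample_objectives=evals)
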