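"""Load–displacement curve analysis and study-level statistics.

Strength is the maximum compressive force on the curve; stiffness is
the least-squares slope over the 20–80 % force sub-window of the
elastic region.  Curve-comparison metrics are a peak-normalized RMSE
(in percent) and a trapezoid-rule normalized error integral used by the
global calibration objective.
"""

from __future__ import annotations

import importlib.resources
import json
import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FORCE_FLOOR_KN = 1e-6
COMMON_GRID_POINTS = 200

LESION_TYPES = ("S", "L", "M")


@dataclass
class LoadDisplacementCurve:
    """Displacement (mm, non-decreasing) vs force (kN) samples."""

    displacement: np.ndarray
    force: np.ndarray

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape or self.displacement.ndim != 1:
            raise ValueError("displacement and force must be equal-length 1-D arrays")
        if len(self.displacement) < 3:
            raise ValueError("a curve needs at least 3 samples")
        if np.any(np.diff(self.displacement) < -1e-12):
            raise ValueError("displacement must be non-decreasing")

    @classmethod
    def from_csv(cls, path) -> "LoadDisplacementCurve":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1])

    def to_csv(self, path) -> None:
        lines = ["displacement_mm,force_kN"]
        lines += [f"{d:.9g},{f:.9g}" for d, f in zip(self.displacement, self.force)]
        pathlib.Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class SpecimenRecord:
    """One study specimen (lesion type S/L/M, BMD, strength, stiffness)."""

    id: str
    level: str
    lesion_type: str
    bmd: float
    strength: float
    stiffness: float

    def __post_init__(self):
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(f"lesion_type must be one of {LESION_TYPES}")
        for f in ("bmd", "strength", "stiffness"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def load_specimen_table() -> pd.DataFrame:
    """Packaged specimen table (demographics, BMD, strength, stiffness).

    Note: the source report's osteosclerotic summary statistics are not
    all arithmetically reproducible from this table under any single
    grouping of the VA15-S T11 specimen (its stiffness matches the
    'mixed' summary); downstream statistics are computed from the rows
    as printed.
    """
    with importlib.resources.files("hfevert").joinpath("data/specimen_table.csv").open() as fh:
        return pd.read_csv(fh)


# ----------------------------------------------------------------------
# curve descriptors
# ----------------------------------------------------------------------

def extract_strength(curve: LoadDisplacementCurve) -> float:
    """Failure strength: maximal compressive force on the curve (kN)."""
    if len(curve.force) == 0:
        raise ValueError("empty curve")
    return float(np.max(curve.force))


def elastic_region_end(curve: LoadDisplacementCurve, tangent_drop: float = 0.5) -> int:
    """Index bounding the elastic region.

    The region ends where the local tangent first drops below
    ``tangent_drop`` times the running peak tangent; if it never does,
    the whole curve is elastic.
    """
    d, f = curve.displacement, curve.force
    dd = np.diff(d)
    good = dd > 1e-12
    tang = np.where(good, np.diff(f) / np.where(good, dd, 1.0), np.nan)
    if len(tang) >= 5:  # light smoothing against sampling noise
        kernel = np.ones(3) / 3.0
        tang = np.convolve(np.nan_to_num(tang, nan=0.0), kernel, mode="same")
    peak = -np.inf
    for i, t in enumerate(tang):
        if not np.isfinite(t):
            continue
        peak = max(peak, t)
        if peak > 0 and t < tangent_drop * peak and i > 1:
            return i
    return len(d) - 1


def extract_stiffness(curve: LoadDisplacementCurve, window=(0.2, 0.8),
                      tangent_drop: float = 0.5) -> float:
    """Stiffness (kN/mm): regression slope over the ``window`` force
    sub-window of the elastic region."""
    end = elastic_region_end(curve, tangent_drop)
    d = curve.displacement[: end + 1]
    f = curve.force[: end + 1]
    fmax = f.max()
    if fmax <= FORCE_FLOOR_KN:
        raise ValueError("no force signal in the elastic region")
    lo, hi = window[0] * fmax, window[1] * fmax
    sel = (f >= lo) & (f <= hi)
    if sel.sum() < 2:
        raise ValueError("too few samples in the stiffness window")
    slope, _ = np.polyfit(d[sel], f[sel], 1)
    return float(slope)


# ----------------------------------------------------------------------
# curve comparison
# ----------------------------------------------------------------------

def _common_grid(sim: LoadDisplacementCurve, ref: LoadDisplacementCurve,
                 n: int = COMMON_GRID_POINTS):
    lo = max(sim.displacement.min(), ref.displacement.min())
    hi = min(sim.displacement.max(), ref.displacement.max())
    if hi <= lo:
        raise ValueError("curves have disjoint displacement ranges")
    grid = np.linspace(lo, hi, n)
    fs = np.interp(grid, sim.displacement, sim.force)
    fr = np.interp(grid, ref.displacement, ref.force)
    return grid, fs, fr


def curve_rmse(sim: LoadDisplacementCurve, ref: LoadDisplacementCurve,
               n: int = COMMON_GRID_POINTS) -> float:
    """RMSE of force differences on a common displacement grid,
    normalized by the reference peak force, in percent."""
    _, fs, fr = _common_grid(sim, ref, n)
    rmse = np.sqrt(np.mean((fs - fr) ** 2))
    return float(100.0 * rmse / np.max(ref.force))


def normalized_error(sim: LoadDisplacementCurve, ref: LoadDisplacementCurve,
                     n: int = COMMON_GRID_POINTS) -> float:
    """Trapezoid integral of |F_sim - F_ref| / F_ref up to the reference
    failure displacement (dimensionless)."""
    d_fail = ref.displacement[int(np.argmax(ref.force))]
    grid = np.linspace(ref.displacement.min(), d_fail, n)
    fs = np.interp(grid, sim.displacement, sim.force)
    fr = np.interp(grid, ref.displacement, ref.force)
    ok = fr > FORCE_FLOOR_KN
    integrand = np.where(ok, np.abs(fs - fr) / np.where(ok, fr, 1.0), 0.0)
    return float(np.trapezoid(integrand, grid))


# ----------------------------------------------------------------------
# study statistics
# ----------------------------------------------------------------------

def group_stats(records: pd.DataFrame, lesion_type: str,
                fields=("bmd_mgHA_cm3", "strength_kN", "stiffness_kN_mm")) -> dict:
    """Mean and sample (n-1) SD per field for one lesion-type group."""
    grp = records[records["lesion_type"] == lesion_type]
    if len(grp) == 0:
        raise ValueError(f"no records with lesion type {lesion_type!r}")
    out = {"n": int(len(grp)), "single_record": len(grp) == 1}
    for f in fields:
        vals = grp[f].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out[f] = {"mean": float(np.mean(vals)), "sd": sd}
    return out


def regression_agreement(predicted, measured) -> dict:
    """OLS of measured on predicted: R², slope, intercept, two-sided p."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if len(predicted) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(predicted) == 0:
        raise ValueError("zero variance in predictor")
    res = stats.linregress(predicted, measured)
    return {"r2": float(res.rvalue ** 2), "slope": float(res.slope),
            "intercept": float(res.intercept), "p": float(res.pvalue)}


def report_json(obj, path) -> None:
    pathlib.Path(path).write_text(json.dumps(obj, indent=2) + "\n")
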