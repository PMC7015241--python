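"""Actin binding, bundling and filament kinetics.

Co-sedimentation binding isotherm fitting (Kd), the low/high-speed
sedimentation partition that separates bundled, filamentous and soluble
actin, pyrene-fluorescence polymerization-rate extraction, and
Latrunculin-A-induced depolymerization kinetics with protection
quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import binding_fraction

__all__ = [
    "BindingFit",
    "fit_binding_isotherm",
    "BundlingPartition",
    "partition_bundling",
    "normalize_polymerization",
    "polymerization_rate",
    "normalize_depolymerization",
    "depolymerization_decrease",
    "RateResult",
]


# ---------------------------------------------------------------------------
# Binding


@dataclass
class BindingFit:
    actin_um: np.ndarray
    bound_frac: np.ndarray
    kd_um: float | None
    kd_se_um: float | None
    residuals: np.ndarray | None
    model: str
    ligand_um: float
    no_binding: bool = False
    message: str = ""


def _depletion_bound_frac(actin_um, kd_um, ligand_um):
    """Bound-ligand fraction with ligand depletion: the quadratic solution
    of L + A <-> LA at total ligand concentration ``ligand_um``."""
    a = np.asarray(actin_um, dtype=float)
    s = ligand_um + a + kd_um
    complex_um = 0.5 * (s - np.sqrt(s * s - 4.0 * ligand_um * a))
    return complex_um / ligand_um


def fit_binding_isotherm(
    actin_um,
    bound_frac,
    ligand_um: float = 10.0,
    model: str = "simple",
    no_binding_threshold: float = 0.05,
) -> BindingFit:
    """Fit the fraction of ligand co-sedimenting with F-actin.

    The default single-site model f([A]) = [A]/([A] + Kd) treats free actin
    as the total concentration (no ligand depletion); ``model="depletion"``
    uses the quadratic binding solution at the assay ligand concentration.
    Data with no measurable saturation (all fractions below
    ``no_binding_threshold``) are reported as a no-binding result, matching
    domains that do not pellet with F-actin, rather than forcing a Kd.
    """
    a = np.asarray(actin_um, dtype=float)
    f = np.asarray(bound_frac, dtype=float)
    if a.size < 4:
        raise ValueError("need at least 4 actin concentrations")
    if a.max() / max(a.min(), 1e-12) < 5.0:
        raise ValueError("actin concentrations must span at least a 5-fold range")
    if np.any(a < 0):
        raise ValueError("negative actin concentrations")
    if model not in ("simple", "depletion"):
        raise ValueError("model must be 'simple' or 'depletion'")
    if f.max() < no_binding_threshold:
        return BindingFit(a, f, None, None, None, model, ligand_um,
                          no_binding=True, message="no measurable Kd")

    if model == "simple":
        func = binding_fraction
    else:
        def func(x, kd):
            return _depletion_bound_frac(x, kd, ligand_um)

    # Start near the concentration at half-saturation
    kd0 = float(a[np.argmin(np.abs(f - 0.5))])
    popt, pcov = curve_fit(func, a, f, p0=[max(kd0, 1e-3)],
                           bounds=(1e-9, np.inf), maxfev=20000)
    kd = float(popt[0])
    resid = f - func(a, kd)
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.nan
    return BindingFit(a, f, kd, se, resid, model, ligand_um)


# ---------------------------------------------------------------------------
# Bundling partition


@dataclass
class BundlingPartition:
    low_speed_pellet: float
    high_speed_pellet: float
    supernatant: float
    bundled_frac: float
    filamentous_frac: float
    soluble_frac: float


def partition_bundling(low_pellet, high_pellet, supernatant) -> BundlingPartition:
    """Fractions of actin in each sedimentation compartment: the low-speed
    pellet holds bundled filaments, the high-speed pellet single filaments,
    the supernatant soluble actin."""
    vals = np.array([low_pellet, high_pellet, supernatant], dtype=float)
    if np.any(vals < 0):
        raise ValueError("band densities must be non-negative")
    total = vals.sum()
    if total == 0:
        raise ValueError("all compartments are zero")
    fr = vals / total
    return BundlingPartition(*vals, bundled_frac=float(fr[0]),
                             filamentous_frac=float(fr[1]), soluble_frac=float(fr[2]))


# ---------------------------------------------------------------------------
# Kinetic traces


def _check_trace(time_s: np.ndarray) -> None:
    if np.any(np.diff(time_s) <= 0):
        raise ValueError("time must be strictly increasing")


def normalize_polymerization(
    trace: pd.DataFrame, k: int = 5, plateau_slope_tol: float = 1e-3
) -> pd.DataFrame:
    """Normalize a polymerization trace to [0, 1]:
    f = (F − baseline)/(plateau − baseline) with the baseline the mean of
    the first ``k`` points and the plateau the mean of the last ``k``.

    Requires the trace to have reached a plateau: the terminal slope (OLS
    over the trailing 10% of points, at least ``k``) must stay below
    ``plateau_slope_tol`` of the fluorescence range per second.
    """
    t = np.asarray(trace["time_s"], dtype=float)
    f = np.asarray(trace["rfu"], dtype=float)
    _check_trace(t)
    if k < 2 or 2 * k > t.size:
        raise ValueError("k must satisfy 2 <= k <= n/2")
    baseline = float(f[:k].mean())
    plateau = float(f[-k:].mean())
    if plateau <= baseline:
        raise ValueError("plateau must exceed baseline")
    m = max(k, t.size // 10)
    tc = t[-m:] - t[-m:].mean()
    end_slope = abs(float(np.dot(tc, f[-m:]) / np.dot(tc, tc)))
    if end_slope > plateau_slope_tol * (plateau - baseline):
        raise ValueError("trace has not reached a plateau")
    out = trace.copy()
    out["rfu"] = (f - baseline) / (plateau - baseline)
    return out


@dataclass
class RateResult:
    rate: float
    units: str
    window: tuple[float, float]
    slope_per_s: float | None = None
    rate_free: float | None = None
    rate_plus: float | None = None
    percent_decrease: float | None = None
    config: dict = field(default_factory=dict)


def polymerization_rate(
    trace_norm: pd.DataFrame,
    total_actin_um: float,
    c_crit_um: float = 0.1,
    window_frac: float = 0.1,
    band: tuple[float, float] = (0.1, 0.6),
) -> RateResult:
    """Overall polymerization rate from the linear region of a normalized
    trace, converted from relative fluorescence per second to nM actin/s.

    The linear region is the steepest sliding window (width
    ``window_frac``·n points) whose normalized values lie entirely within
    ``band``; the default 10–60% band avoids the nucleation lag and the
    plateau roll-off.  Conversion assumes the normalized signal is
    proportional to polymerized actin between the critical concentration
    and the total: rate = slope · (total − c_crit) · 1000.
    """
    t = np.asarray(trace_norm["time_s"], dtype=float)
    f = np.asarray(trace_norm["rfu"], dtype=float)
    _check_trace(t)
    if total_actin_um <= c_crit_um:
        raise ValueError("total_actin_um must exceed c_crit_um")
    w = max(3, int(round(window_frac * t.size)))
    lo, hi = band
    best_slope = None
    best_win = None
    for i in range(0, t.size - w + 1):
        seg_f = f[i : i + w]
        if seg_f.min() < lo or seg_f.max() > hi:
            continue
        seg_t = t[i : i + w]
        tc = seg_t - seg_t.mean()
        slope = float(np.dot(tc, seg_f) / np.dot(tc, tc))
        if best_slope is None or slope > best_slope:
            best_slope = slope
            best_win = (float(seg_t[0]), float(seg_t[-1]))
    if best_slope is None:
        raise ValueError("no sliding window lies within the linear band")
    rate = best_slope * (total_actin_um - c_crit_um) * 1000.0
    return RateResult(
        rate=rate, units="nM/s", window=best_win, slope_per_s=best_slope,
        config={"c_crit_um": c_crit_um, "window_frac": window_frac, "band": band},
    )


def normalize_depolymerization(trace: pd.DataFrame, lata_final: float) -> pd.DataFrame:
    """Normalize a depolymerization trace on the Latrunculin-A convention:
    the final fluorescence of fully disassembled F-actin maps to 0 and the
    maximum of the data set to 1."""
    t = np.asarray(trace["time_s"], dtype=float)
    f = np.asarray(trace["rfu"], dtype=float)
    _check_trace(t)
    fmax = float(f.max())
    if fmax <= lata_final:
        raise ValueError("maximum fluorescence must exceed the final LatA level")
    out = trace.copy()
    out["rfu"] = (f - lata_final) / (fmax - lata_final)
    return out


def _initial_slope(t: np.ndarray, f: np.ndarray, window_s: float) -> float:
    mask = t <= t[0] + window_s
    if mask.sum() < 3:
        raise ValueError("initial-rate window contains fewer than 3 points")
    tw = t[mask]
    fw = f[mask]
    tc = tw - tw.mean()
    return float(np.dot(tc, fw) / np.dot(tc, tc))


def _exponential_rate(t: np.ndarray, f: np.ndarray) -> float:
    t0 = t[0]
    popt, _ = curve_fit(lambda x, k: np.exp(-k * (x - t0)), t, f,
                        p0=[1e-3], bounds=(1e-12, np.inf), maxfev=20000)
    return float(popt[0])


def depolymerization_decrease(
    protein_free: pd.DataFrame,
    protein_plus: pd.DataFrame,
    window_s: float = 60.0,
    method: str = "initial_slope",
) -> RateResult:
    """Percent decrease of the disassembly rate caused by a bound protein.

    Both traces must already be normalized on the depolymerization
    convention.  The default rate is the magnitude of the OLS slope over
    the first ``window_s`` seconds (initial linear rate); ``method=
    "exponential"`` fits a single-exponential decay to the full trace and
    compares rate constants instead.  percent_decrease =
    100·(1 − rate_plus/rate_free).
    """
    tf = np.asarray(protein_free["time_s"], dtype=float)
    ff = np.asarray(protein_free["rfu"], dtype=float)
    tp = np.asarray(protein_plus["time_s"], dtype=float)
    fp = np.asarray(protein_plus["rfu"], dtype=float)
    _check_trace(tf)
    _check_trace(tp)
    if method == "initial_slope":
        rate_free = -_initial_slope(tf, ff, window_s)
        rate_plus = -_initial_slope(tp, fp, window_s)
        units = "1/s (initial slope of normalized trace)"
    elif method == "exponential":
        rate_free = _exponential_rate(tf, ff)
        rate_plus = _exponential_rate(tp, fp)
        units = "1/s (exponential rate constant)"
    else:
        raise ValueError("method must be 'initial_slope' or 'exponential'")
    if rate_free <= 0:
        raise ValueError("protein-free disassembly rate is non-positive")
    pct = 100.0 * (1.0 - rate_plus / rate_free)
    return RateResult(
        rate=rate_free, units=units, window=(float(tf[0]), float(tf[0]) + window_s),
        rate_free=rate_free, rate_plus=rate_plus, percent_decrease=pct,
        config={"window_s": window_s, "method": method},
    )
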