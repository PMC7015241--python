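"""Whole-muscle geometry and contractile analysis.

Covers pennation-corrected muscle cross-sectional area from wet weight,
least-squares fitting of the Hill hyperbolic force–velocity relation,
power-curve extraction with the closed-form optimum load, and summaries of
eccentric-contraction injury protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import hill_velocity

__all__ = [
    "MuscleProfile",
    "MUSCLE_PROFILES",
    "MuscleGeometry",
    "HillHyperbolaFit",
    "PowerCurve",
    "EccentricSeries",
    "estimate_muscle_csa",
    "specific_force_kn_m2",
    "fit_hill_force_velocity",
    "power_from_fit",
    "summarize_eccentric",
]


@dataclass(frozen=True)
class MuscleProfile:
    """Architectural constants of a muscle: pennation angle (degrees),
    fibre-length/muscle-length ratio, and density (g/cm³)."""

    theta_deg: float
    lf_factor: float
    delta_g_cm3: float = 1.056


# Mouse hind-limb profiles used for wet-weight CSA estimates.
MUSCLE_PROFILES = {
    "edl": MuscleProfile(theta_deg=8.3, lf_factor=0.51),
    "soleus": MuscleProfile(theta_deg=8.7, lf_factor=0.75),
}


@dataclass
class MuscleGeometry:
    w_g: float
    l0_cm: float
    theta_deg: float
    lf_factor: float
    delta_g_cm3: float
    lf_cm: float
    csa_cm2: float


def estimate_muscle_csa(
    w_g: float,
    l0_cm: float,
    muscle: str | None = None,
    *,
    theta_deg: float | None = None,
    lf_factor: float | None = None,
    delta_g_cm3: float = 1.056,
) -> MuscleGeometry:
    """Physiological CSA from wet weight: CSA = w·cosθ / (Lf·δ), with
    Lf = lf_factor·L0.

    Either name a built-in ``muscle`` profile ("edl", "soleus") or supply
    ``theta_deg`` and ``lf_factor`` explicitly.
    """
    if muscle is not None:
        key = muscle.lower()
        if key not in MUSCLE_PROFILES:
            raise ValueError(
                f"unknown muscle profile {muscle!r}; known: {sorted(MUSCLE_PROFILES)}"
            )
        prof = MUSCLE_PROFILES[key]
        theta_deg = prof.theta_deg
        lf_factor = prof.lf_factor
        delta_g_cm3 = prof.delta_g_cm3
    if theta_deg is None or lf_factor is None:
        raise ValueError("supply a muscle profile name or both theta_deg and lf_factor")
    if w_g <= 0 or l0_cm <= 0 or lf_factor <= 0 or delta_g_cm3 <= 0:
        raise ValueError("w_g, l0_cm, lf_factor and delta_g_cm3 must be positive")
    if not 0.0 <= theta_deg < 90.0:
        raise ValueError("theta_deg must lie in [0, 90)")
    lf = lf_factor * l0_cm
    csa = w_g * math.cos(math.radians(theta_deg)) / (lf * delta_g_cm3)
    return MuscleGeometry(w_g, l0_cm, theta_deg, lf_factor, delta_g_cm3, lf, csa)


def specific_force_kn_m2(t0_mn: float, csa_cm2: float) -> float:
    """Specific force T0/CSA in kN/m² from T0 in mN and CSA in cm²
    (1 mN/cm² = 10 N/m² = 10⁻² kN/m²)."""
    if csa_cm2 <= 0:
        raise ValueError("csa_cm2 must be positive")
    return t0_mn / csa_cm2 * 1e-2


@dataclass
class HillHyperbolaFit:
    """Fitted parameters of (T + a)(V + b) = (V0 + b)·a.

    ``a`` carries force units, ``b`` and ``v0`` velocity units; ``t0`` is
    the isometric force used only for normalization (``a_over_t0``); the
    hyperbola is not constrained through (T0, 0).
    """

    a: float
    b: float
    v0: float
    t0: float
    a_over_t0: float
    rss: float
    param_se: dict = field(default_factory=dict)
    converged: bool = True
    message: str = ""
    units: dict = field(default_factory=lambda: {"force": "mN", "velocity": "L0/s"})

    def predict(self, load) -> np.ndarray:
        return hill_velocity(load, self.a, self.b, self.v0)

    @property
    def t_max(self) -> float:
        """Load at which the fitted hyperbola predicts zero velocity."""
        return self.a * self.v0 / self.b


def fit_hill_force_velocity(
    loads,
    velocities,
    t0: float,
    max_restarts: int = 10,
    seed: int = 0,
) -> HillHyperbolaFit:
    """Ordinary least squares on velocity residuals against the Hill
    hyperbola, with a, b, V0 free positive regression parameters.

    Starts from a = 0.25·T0, V0 = max observed velocity, b = a·V0/T0, with
    up to ``max_restarts`` seeded random restarts on non-convergence; a
    persistently failing fit is returned flagged, not raised.
    """
    loads = np.asarray(loads, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if loads.size < 4:
        raise ValueError("need at least 4 load–velocity points")
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    if np.any(loads <= 0) or np.any(loads > t0 * (1 + 1e-9)):
        raise ValueError("loads must lie in (0, T0]")
    if np.any(velocities < 0):
        raise ValueError("velocities must be non-negative")

    a0 = 0.25 * t0
    v00 = float(velocities.max())
    b0 = a0 * v00 / t0
    starts = [(a0, b0, v00)]
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        starts.append(
            (
                a0 * rng.uniform(0.3, 3.0),
                b0 * rng.uniform(0.3, 3.0),
                v00 * rng.uniform(0.5, 2.0),
            )
        )

    eps = 1e-12
    best = None
    message = ""
    for p0 in starts:  # random restarts engage only while unconverged
        try:
            popt, pcov = curve_fit(
                hill_velocity, loads, velocities, p0=p0,
                bounds=([eps, eps, eps], [np.inf] * 3), maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:  # non-convergence
            message = str(exc)
            continue
        rss = float(np.sum((velocities - hill_velocity(loads, *popt)) ** 2))
        best = (popt, pcov, rss)
        break
    if best is None:
        return HillHyperbolaFit(
            a=math.nan, b=math.nan, v0=math.nan, t0=t0, a_over_t0=math.nan,
            rss=math.nan, converged=False, message=message or "fit failed",
        )
    popt, pcov, rss = best
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [math.nan] * 3
    return HillHyperbolaFit(
        a=float(popt[0]), b=float(popt[1]), v0=float(popt[2]), t0=t0,
        a_over_t0=float(popt[0]) / t0, rss=rss,
        param_se={"a": float(se[0]), "b": float(se[1]), "v0": float(se[2])},
    )


@dataclass
class PowerCurve:
    loads: np.ndarray
    power: np.ndarray
    wmax: float
    t_at_wmax: float
    t_at_wmax_grid: float


def power_from_fit(fit: HillHyperbolaFit, n_grid: int = 1000) -> PowerCurve:
    """Power W(T) = T·V(T) along the fitted hyperbola.

    The optimum load has the closed form T* = sqrt(a(Tmax + a)) − a with
    Tmax = a·V0/b; the grid argmax is returned alongside as a cross-check.
    The optimum falls near one-third of isometric load for physiological
    curvatures.
    """
    if not fit.converged:
        raise ValueError("cannot build a power curve from a non-converged fit")
    t_max = fit.t_max
    if t_max <= 0:
        raise ValueError("degenerate fit: predicted zero-velocity load <= 0")
    loads = np.linspace(0.0, t_max, n_grid)
    power = loads * fit.predict(loads)
    t_star = math.sqrt(fit.a * (t_max + fit.a)) - fit.a
    wmax = t_star * float(fit.predict(t_star))
    t_grid = float(loads[int(np.argmax(power))])
    return PowerCurve(loads=loads, power=power, wmax=wmax,
                      t_at_wmax=t_star, t_at_wmax_grid=t_grid)


@dataclass
class EccentricSeries:
    pre_iso: np.ndarray
    ec_forces: np.ndarray
    post_iso: np.ndarray
    pre_mean: float
    post_mean: float
    percent_drop: float


def summarize_eccentric(pre_iso, ec_forces, post_iso) -> EccentricSeries:
    """Percent drop in isometric force across an eccentric-contraction
    series: 100·(1 − mean(post)/mean(pre))."""
    pre = np.asarray(pre_iso, dtype=float)
    ec = np.asarray(ec_forces, dtype=float)
    post = np.asarray(post_iso, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("pre_iso and post_iso must be non-empty")
    if np.any(pre <= 0) or np.any(post < 0):
        raise ValueError("isometric forces must be positive")
    pre_mean = float(pre.mean())
    post_mean = float(post.mean())
    return EccentricSeries(
        pre_iso=pre, ec_forces=ec, post_iso=post,
        pre_mean=pre_mean, post_mean=post_mean,
        percent_drop=100.0 * (1.0 - post_mean / pre_mean),
    )
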