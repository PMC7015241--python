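"""Single skinned-fibre mechanics.

Elliptical fibre CSA, half-sarcomere stiffness from the T1 (end-of-step
force vs step size) relation with the strain intercept Y0, the Y0–T0
regression across calcium levels (slope Cf, intercept s0), force–pCa Hill
sigmoid fitting (nH, pK), and the passive Young's modulus as the tangent of
the stress–sarcomere-length curve at 3.0 μm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .synthetic import hill_sigmoid

__all__ = [
    "elliptical_csa",
    "T1Relation",
    "fit_t1_relation",
    "StrainForceRegression",
    "regress_strain_force",
    "ForcePCaFit",
    "fit_force_pca",
    "PassiveFit",
    "passive_young_modulus",
]


def elliptical_csa(d_um: float, h_um: float) -> float:
    """Fibre cross-sectional area (μm²) assuming elliptical geometry,
    CSA = π/4·d·h with width d and height h."""
    if d_um <= 0 or h_um <= 0:
        raise ValueError("fibre width and height must be positive")
    return math.pi / 4.0 * d_um * h_um


@dataclass
class T1Relation:
    steps_nm_hs: np.ndarray
    t1_forces: np.ndarray
    slope: float
    intercept: float
    y0_nm_hs: float
    degenerate: bool = False
    message: str = ""


def fit_t1_relation(steps_nm_hs, t1_forces) -> T1Relation:
    """Ordinary least-squares line through the T1 points.

    The slope is the half-sarcomere stiffness; Y0, the half-sarcomere
    strain, is the magnitude of the abscissa intercept (−intercept/slope).
    A flat relation is returned flagged degenerate rather than raised so
    batch processing can continue.
    """
    x = np.asarray(steps_nm_hs, dtype=float)
    y = np.asarray(t1_forces, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 T1 points")
    if np.ptp(x) == 0:
        raise ValueError("length steps have zero variance")
    xc = x - x.mean()
    slope = float(np.dot(xc, y) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    if slope <= 0:
        return T1Relation(x, y, slope, intercept, math.nan, degenerate=True,
                          message="non-positive stiffness; Y0 undefined")
    return T1Relation(x, y, slope, intercept, abs(-intercept / slope))


@dataclass
class StrainForceRegression:
    t0: np.ndarray
    y0: np.ndarray
    cf: float
    s0: float
    r_value: float
    cf_se: float


def regress_strain_force(t0_values, y0_values) -> StrainForceRegression:
    """Linear regression of half-sarcomere strain Y0 on isometric force T0
    across pCa levels; slope Cf, ordinate intercept s0."""
    t0 = np.asarray(t0_values, dtype=float)
    y0 = np.asarray(y0_values, dtype=float)
    if t0.size < 3:
        raise ValueError("need at least 3 (T0, Y0) pairs")
    res = stats.linregress(t0, y0)
    return StrainForceRegression(
        t0=t0, y0=y0, cf=float(res.slope), s0=float(res.intercept),
        r_value=float(res.rvalue), cf_se=float(res.stderr),
    )


@dataclass
class ForcePCaFit:
    pca: np.ndarray
    t_rel: np.ndarray
    n_h: float
    pk: float
    rss: float
    param_se: dict = field(default_factory=dict)
    converged: bool = True
    message: str = ""

    def predict(self, pca) -> np.ndarray:
        return hill_sigmoid(pca, self.n_h, self.pk)


def fit_force_pca(pca, t_rel, max_restarts: int = 10, seed: int = 0) -> ForcePCaFit:
    """Least-squares fit of the Hill sigmoid
    t_rel = 1/(1 + 10^(nH (pCa − pK))) to tension normalized to the
    saturating-calcium value; nH measures cooperativity, pK the calcium
    sensitivity (predicted tension at pCa = pK is 0.5 by construction)."""
    x = np.asarray(pca, dtype=float)
    y = np.asarray(t_rel, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pCa points")
    if np.all(y <= 0) or np.all(y >= 1):
        raise ValueError("all-zero or all-one tensions: nH and pK unidentifiable")

    # pK start: pCa where tension crosses 0.5 (interpolated on sorted data)
    order = np.argsort(x)
    pk0 = float(np.interp(0.5, y[order][::-1], x[order][::-1])) if np.ptp(y) > 0 else x.mean()
    starts = [(2.0, pk0)]
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        starts.append((rng.uniform(0.5, 8.0), rng.uniform(x.min(), x.max())))

    best = None
    message = ""
    for p0 in starts:  # random restarts engage only while unconverged
        try:
            popt, pcov = curve_fit(
                hill_sigmoid, x, y, p0=p0,
                bounds=([1e-6, x.min() - 2.0], [50.0, x.max() + 2.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            message = str(exc)
            continue
        rss = float(np.sum((y - hill_sigmoid(x, *popt)) ** 2))
        best = (popt, pcov, rss)
        break
    if best is None:
        return ForcePCaFit(x, y, math.nan, math.nan, math.nan,
                           converged=False, message=message or "fit failed")
    popt, pcov, rss = best
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [math.nan] * 2
    return ForcePCaFit(
        pca=x, t_rel=y, n_h=float(popt[0]), pk=float(popt[1]), rss=rss,
        param_se={"n_h": float(se[0]), "pk": float(se[1])},
    )


@dataclass
class PassiveFit:
    sl_um: np.ndarray
    stress_kn_m2: np.ndarray
    coeffs: np.ndarray
    sl_eval_um: float
    sl_slack_um: float
    e_per_um: float
    e_per_strain: float
    failure_sl_um: float


def passive_young_modulus(
    sl_um,
    stress_kn_m2,
    sl_eval_um: float = 3.0,
    sl_slack_um: float = 2.2,
    degree: int = 3,
) -> PassiveFit:
    """Tangent Young's modulus of the passive stress–sarcomere-length curve.

    A low-order polynomial (default cubic) is fitted to stress vs sarcomere
    length and differentiated at ``sl_eval_um`` (3.0 μm by default).  The
    tangent is reported both per μm of sarcomere length and per unit strain,
    using strain = (sl − sl_slack)/sl_slack so that
    dσ/dε = sl_slack · dσ/dsl.  The last recorded sarcomere length is
    returned as the failure point of the stretch-to-failure protocol.
    """
    sl = np.asarray(sl_um, dtype=float)
    stress = np.asarray(stress_kn_m2, dtype=float)
    if sl.size < 4:
        raise ValueError("need at least 4 (sl, stress) points")
    if not sl.min() <= sl_eval_um <= sl.max():
        raise ValueError(f"evaluation point {sl_eval_um} μm outside the data range")
    deg = min(degree, sl.size - 1)
    coeffs = np.polyfit(sl, stress, deg)
    d_per_um = float(np.polyval(np.polyder(coeffs), sl_eval_um))
    return PassiveFit(
        sl_um=sl, stress_kn_m2=stress, coeffs=coeffs,
        sl_eval_um=sl_eval_um, sl_slack_um=sl_slack_um,
        e_per_um=d_per_um, e_per_strain=d_per_um * sl_slack_um,
        failure_sl_um=float(sl.max()),
    )
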