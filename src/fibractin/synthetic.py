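"""Seeded synthetic datasets for every analysis stage.

Each generator draws from the same parametric model its analysis counterpart
fits, so that noiseless output is recovered exactly and noisy output exercises
the estimators under controlled conditions.  :func:`paper_fixtures` packages
named datasets whose ground-truth parameters are calibrated so that the
default analysis pipeline returns published reference values (dissociation
constants, depolymerization-rate decreases, Z-line width increases, myotube
width reduction, qPCR fold induction).

Noise is additive Gaussian on the observable, clipped where the observable is
physically bounded (fractions in [0, 1]).  All randomness flows through an
explicit seed; there is no module-level RNG state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "GeneratorConfig",
    "FixtureSet",
    "gen_force_velocity",
    "gen_force_pca",
    "gen_binding_isotherm",
    "gen_polymerization_trace",
    "gen_depolymerization_pair",
    "gen_zline_profile",
    "gen_zline_profiles",
    "gen_fibre_population",
    "paper_fixtures",
]

FIBRE_TYPES = ("1", "2A", "2B", "2X")


@dataclass(frozen=True)
class GeneratorConfig:
    """Common knobs of every generator.

    Parameters
    ----------
    seed :
        Seed for the NumPy ``default_rng``; identical (seed, parameters)
        pairs reproduce byte-identical tables.
    noise_sd :
        Standard deviation of the additive Gaussian noise, in the units of
        the generated observable.  ``0`` yields noiseless model evaluations.
    n_points :
        Number of abscissa points when no explicit ``grid`` is given.
    grid :
        Explicit abscissa values (loads, pCa, concentrations, times or
        positions depending on the generator); overrides ``n_points``.
    """

    seed: int
    noise_sd: float = 0.0
    n_points: int | None = None
    grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_points is not None and self.n_points <= 0:
            raise ValueError("n_points must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def resolve_grid(self, default: np.ndarray) -> np.ndarray:
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            if g.size == 0:
                raise ValueError("grid must not be empty")
            return g
        if self.n_points is not None:
            lo, hi = float(default[0]), float(default[-1])
            return np.linspace(lo, hi, self.n_points)
        return np.asarray(default, dtype=float)


def _noise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    # Draw even when sd == 0 so noiseless/noisy runs share the RNG stream.
    return sd * rng.standard_normal(n)


# ---------------------------------------------------------------------------
# Mechanics generators


def hill_velocity(load: np.ndarray, a: float, b: float, v0: float) -> np.ndarray:
    """Shortening velocity of the hyperbolic load–velocity relation
    (T + a)(V + b) = (V0 + b) a, solved for V."""
    load = np.asarray(load, dtype=float)
    return a * (v0 + b) / (load + a) - b


def gen_force_velocity(
    a: float, b: float, v0: float, t0: float, config: GeneratorConfig
) -> pd.DataFrame:
    """Load–velocity points from a Hill hyperbola.

    Loads default to 9 values spanning (0, 0.95·T0]; velocities are the
    model evaluations plus Gaussian noise of sd ``config.noise_sd``
    (velocity units).
    """
    for name, val in (("a", a), ("b", b), ("v0", v0), ("t0", t0)):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val!r}")
    loads = config.resolve_grid(np.linspace(0.05, 0.95, 9) * t0)
    v = hill_velocity(loads, a, b, v0) + _noise(config.rng(), config.noise_sd, loads.size)
    return pd.DataFrame({"load": loads, "velocity": v})


def hill_sigmoid(pca: np.ndarray, n_h: float, pk: float) -> np.ndarray:
    """Relative tension of the force–pCa Hill sigmoid, 1/(1 + 10^(nH (pCa − pK)))."""
    pca = np.asarray(pca, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (n_h * (pca - pk)))


def gen_force_pca(n_h: float, pk: float, config: GeneratorConfig) -> pd.DataFrame:
    """pCa vs relative tension points from the Hill sigmoid, clipped to [0, 1].

    The default grid spans the activating range pCa 6.5–4.5.
    """
    if n_h <= 0:
        raise ValueError("n_h must be positive")
    pca = config.resolve_grid(np.linspace(6.5, 4.5, 9))
    t_rel = hill_sigmoid(pca, n_h, pk) + _noise(config.rng(), config.noise_sd, pca.size)
    if config.noise_sd > 0:
        t_rel = np.clip(t_rel, 0.0, 1.0)
    return pd.DataFrame({"pca": pca, "t_rel": t_rel})


# ---------------------------------------------------------------------------
# Biochemistry generators


def binding_fraction(actin_um: np.ndarray, kd_um: float) -> np.ndarray:
    """Single-site saturation isotherm f([A]) = [A] / ([A] + Kd)."""
    actin_um = np.asarray(actin_um, dtype=float)
    return actin_um / (actin_um + kd_um)


DEFAULT_ACTIN_GRID = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 25.0, 30.0)


def gen_binding_isotherm(
    kd_um: float,
    config: GeneratorConfig,
    actin_grid: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Actin concentration vs bound-ligand fraction from a single-site
    isotherm; default concentrations cover the co-sedimentation range
    1–30 μM."""
    if kd_um <= 0:
        raise ValueError("kd_um must be positive")
    grid = np.asarray(actin_grid if actin_grid is not None else DEFAULT_ACTIN_GRID, float)
    grid = config.resolve_grid(grid)
    if np.any(grid < 0):
        raise ValueError("actin concentrations must be non-negative")
    f = binding_fraction(grid, kd_um) + _noise(config.rng(), config.noise_sd, grid.size)
    if config.noise_sd > 0:
        f = np.clip(f, 0.0, 1.0)
    return pd.DataFrame({"actin_um": grid, "bound_frac": f})


def gen_polymerization_trace(
    k_obs: float,
    lag_s: float,
    plateau_rfu: float,
    baseline_rfu: float,
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Pyrene-fluorescence polymerization trace: baseline through a lag
    phase, then a single-exponential rise to plateau.

    F(t) = baseline + (plateau − baseline) · max(0, 1 − exp(−k_obs (t − lag))).
    """
    if k_obs <= 0:
        raise ValueError("k_obs must be positive")
    if plateau_rfu <= baseline_rfu:
        raise ValueError("plateau_rfu must exceed baseline_rfu")
    t = config.resolve_grid(np.arange(0.0, 1801.0, 2.0))
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    rise = np.where(t > lag_s, 1.0 - np.exp(-k_obs * (t - lag_s)), 0.0)
    f = baseline_rfu + (plateau_rfu - baseline_rfu) * rise
    f = f + _noise(config.rng(), config.noise_sd, t.size)
    return pd.DataFrame({"time_s": t, "rfu": f})


def gen_depolymerization_pair(
    k0: float,
    protection: float,
    config: GeneratorConfig,
    baseline_rfu: float = 50.0,
    max_rfu: float = 1050.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latrunculin-A depolymerization trace pair (protein-free, protein-plus).

    On the normalized scale the traces decay as exp(−k0 t) and
    exp(−k0 (1 − protection) t) over 600 s; both are mapped back to raw RFU
    with the stated baseline (the final LatA level of fully disassembled
    F-actin) and maximum.
    """
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    if not 0.0 <= protection < 1.0:
        raise ValueError("protection must lie in [0, 1)")
    if max_rfu <= baseline_rfu:
        raise ValueError("max_rfu must exceed baseline_rfu")
    t = config.resolve_grid(np.arange(0.0, 601.0, 1.0))
    rng = config.rng()
    out = []
    for k in (k0, k0 * (1.0 - protection)):
        f_norm = np.exp(-k * t)
        rfu = baseline_rfu + (max_rfu - baseline_rfu) * f_norm
        rfu = rfu + _noise(rng, config.noise_sd, t.size)
        out.append(pd.DataFrame({"time_s": t, "rfu": rfu}))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Morphometry generators


def trapezoid_profile(
    position_nm: np.ndarray,
    width_nm: float,
    peak_amp: float,
    background: float,
    shoulder_frac: float = 0.2,
    center_nm: float | None = None,
) -> np.ndarray:
    """Trapezoidal density peak on a flat background.

    ``width_nm`` is the width at the base (outer extent of the shoulders);
    each linear shoulder occupies ``shoulder_frac``·width, the plateau the
    remainder.
    """
    position_nm = np.asarray(position_nm, dtype=float)
    if width_nm <= 0:
        raise ValueError("width_nm must be positive")
    if not 0.0 <= shoulder_frac < 0.5:
        raise ValueError("shoulder_frac must lie in [0, 0.5)")
    c = 0.5 * (position_nm[0] + position_nm[-1]) if center_nm is None else center_nm
    half_base = 0.5 * width_nm
    shoulder = shoulder_frac * width_nm
    half_top = half_base - shoulder
    x = np.abs(position_nm - c)
    if shoulder == 0:
        frac = (x <= half_base).astype(float)
    else:
        frac = np.clip((half_base - x) / shoulder, 0.0, 1.0)
    return background + peak_amp * frac


def gen_zline_profile(
    width_nm: float,
    peak_amp: float,
    background: float,
    config: GeneratorConfig,
    shoulder_frac: float = 0.2,
    span_nm: float = 400.0,
    dx_nm: float = 0.05,
) -> pd.DataFrame:
    """Averaged Z-line density profile: trapezoid peak centred on a flat
    background, sampled every ``dx_nm``, with pointwise Gaussian noise."""
    if config.grid is not None:
        pos = np.asarray(config.grid, dtype=float)
    else:
        pos = np.arange(0.0, span_nm + 0.5 * dx_nm, dx_nm)
    if width_nm >= pos[-1] - pos[0]:
        raise ValueError("width_nm exceeds the profile support")
    inten = trapezoid_profile(pos, width_nm, peak_amp, background, shoulder_frac)
    inten = inten + _noise(config.rng(), config.noise_sd, pos.size)
    return pd.DataFrame({"position_nm": pos, "intensity": inten})


def gen_zline_profiles(
    width_wt_nm: float,
    scale_mko: float,
    peak_amp: float,
    background: float,
    config: GeneratorConfig,
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """WT/MKO Z-line profile pair; the knockout base width (and its
    shoulders with it) is ``scale_mko`` times the wild-type width."""
    wt = gen_zline_profile(width_wt_nm, peak_amp, background, config, **kwargs)
    mko_cfg = GeneratorConfig(
        seed=config.seed + 1, noise_sd=config.noise_sd,
        n_points=config.n_points, grid=config.grid,
    )
    mko = gen_zline_profile(width_wt_nm * scale_mko, peak_amp, background, mko_cfg, **kwargs)
    return wt, mko


def gen_fibre_population(
    mu_log: float,
    sigma_log: float,
    n_fibres: int,
    type_props: tuple[float, ...],
    config: GeneratorConfig,
    muscle: str = "EDL",
    genotype: str = "WT",
    csa_scale: float = 1.0,
) -> pd.DataFrame:
    """Per-fibre CSA table with fibre-type labels.

    CSA is log-normal per fibre (``exp(N(mu_log, sigma_log))`` μm², scaled
    by ``csa_scale``); fibre types are a multinomial draw with proportions
    ``type_props`` over type labels 1, 2A, 2B, 2X.
    """
    if n_fibres <= 0:
        raise ValueError("n_fibres must be positive")
    props = np.asarray(type_props, dtype=float)
    if props.size > len(FIBRE_TYPES):
        raise ValueError(f"at most {len(FIBRE_TYPES)} fibre types supported")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("type_props must sum to 1")
    rng = config.rng()
    csa = csa_scale * np.exp(mu_log + sigma_log * rng.standard_normal(n_fibres))
    types = rng.choice(FIBRE_TYPES[: props.size], size=n_fibres, p=props)
    return pd.DataFrame(
        {"csa_um2": csa, "fibre_type": types, "muscle": muscle, "genotype": genotype}
    )


# ---------------------------------------------------------------------------
# Packaged fixtures


@dataclass
class FixtureSet:
    """A named bundle of tables plus the ground truth that generated them."""

    name: str
    ground_truth: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)  # table name -> DataFrame
    params: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Write each table as ``<name>__<table>.csv`` plus a JSON metadata
        sidecar recording generator parameters, seed and ground truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for table, df in self.files.items():
            df.to_csv(out / f"{self.name}__{table}.csv", index=False)
        meta = {
            "fixture": self.name,
            "ground_truth": self.ground_truth,
            "params": self.params,
        }
        (out / f"{self.name}.meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc = t - t.mean()
    return float(np.dot(tc, y) / np.dot(tc, tc))


def calibrate_protection(
    target_pct: float, k0: float, window_s: float = 60.0, dt_s: float = 1.0
) -> float:
    """Protection factor such that the default initial-rate pipeline (OLS
    slope of the normalized decay over the first ``window_s`` seconds)
    measures exactly ``target_pct`` percent decrease.

    Because the decay is exponential, the OLS slope over a finite window is
    not proportional to the rate constant, so the protection is found by a
    1-D root search rather than set to ``target_pct/100`` directly.
    """
    t = np.arange(0.0, window_s + 0.5 * dt_s, dt_s)
    slope_free = _ols_slope(t, np.exp(-k0 * t))

    def gap(k_plus: float) -> float:
        ratio = _ols_slope(t, np.exp(-k_plus * t)) / slope_free
        return 100.0 * (1.0 - ratio) - target_pct

    k_plus = brentq(gap, 1e-9, k0)
    return 1.0 - k_plus / k0


def _depoly_fixture(name: str, ratio: str, target_pct: float, seed: int) -> FixtureSet:
    k0 = 0.01  # 1/s: full disassembly of the free trace within 600 s
    protection = calibrate_protection(target_pct, k0)
    cfg = GeneratorConfig(seed=seed, noise_sd=0.0)
    free, plus = gen_depolymerization_pair(k0, protection, cfg)
    return FixtureSet(
        name=name,
        ground_truth={"percent_decrease": target_pct, "k0_per_s": k0,
                      "protection": protection},
        files={"free": free, "plus": plus},
        params={"molar_ratio": ratio, "seed": seed, "noise_sd": 0.0,
                "baseline_rfu": 50.0, "max_rfu": 1050.0,
                "rate_window_s": 60.0},
    )


def _binding_fixture(name: str, kd_um: float, seed: int) -> FixtureSet:
    cfg = GeneratorConfig(seed=seed, noise_sd=0.0)
    iso = gen_binding_isotherm(kd_um, cfg)
    return FixtureSet(
        name=name,
        ground_truth={"kd_um": kd_um},
        files={"isotherm": iso},
        params={"ligand_um": 10.0, "seed": seed, "noise_sd": 0.0},
    )


def _zline_fixture(name: str, pct_increase: float, seed: int) -> FixtureSet:
    # Base widths chosen so every trapezoid breakpoint lands on the 0.05-nm
    # sample grid for both genotypes: the threshold-crossing interpolation is
    # then exact and the measured ratio equals the true ratio.
    width_wt = 50.0
    scale = 1.0 + pct_increase / 100.0
    cfg = GeneratorConfig(seed=seed, noise_sd=0.0)
    wt, mko = gen_zline_profiles(width_wt, scale, peak_amp=100.0, background=20.0,
                                 config=cfg)
    return FixtureSet(
        name=name,
        ground_truth={"percent_increase": pct_increase,
                      "width_wt_nm": width_wt, "width_mko_nm": width_wt * scale},
        files={"wt": wt, "mko": mko},
        params={"peak_amp": 100.0, "background": 20.0, "shoulder_frac": 0.2,
                "dx_nm": 0.05, "seed": seed, "noise_sd": 0.0},
    )


def _myotube_fixture(seed: int) -> FixtureSet:
    # Paired scaling: the knockout sample is the wild-type draws times 0.64,
    # so the mean reduction equals the fixture truth exactly at any n.
    rng = np.random.default_rng(seed)
    n = 250
    wt = np.exp(np.log(18.0) + 0.25 * rng.standard_normal(n))  # μm
    scale = 0.64
    mko = scale * wt
    df = pd.DataFrame({
        "width_um": np.concatenate([wt, mko]),
        "genotype": ["WT"] * n + ["MKO"] * n,
    })
    return FixtureSet(
        name="myotube_width",
        ground_truth={"percent_reduction": 100.0 * (1.0 - scale)},
        files={"widths": df},
        params={"n_per_genotype": n, "median_wt_um": 18.0, "sigma_log": 0.25,
                "paired_scale": scale, "seed": seed},
    )


def _ddct_fixture(seed: int) -> FixtureSet:
    fold = 2.5
    ref_ct = 18.0
    dct_cal = 6.0
    dct_test = dct_cal - math.log2(fold)
    rows = []
    for i in range(3):
        rows.append(("prol_%d" % (i + 1), ref_ct + dct_cal, ref_ct, "calibrator"))
        rows.append(("diff_%d" % (i + 1), ref_ct + dct_test, ref_ct, "test"))
    df = pd.DataFrame(rows, columns=["sample", "target_ct", "ref_ct", "group"])
    return FixtureSet(
        name="ddct_2p5fold",
        ground_truth={"fold_change": fold},
        files={"ct": df},
        params={"ref_ct": ref_ct, "seed": seed, "noise_sd": 0.0},
    )


def _fibre_csa_fixture(seed: int) -> FixtureSet:
    # Same paired-scaling rationale as the myotube fixture: 0.52 scale gives
    # exactly the 48% mean CSA reduction of the fixture truth.
    scale = 0.52
    cfg = GeneratorConfig(seed=seed)
    wt = gen_fibre_population(math.log(1800.0), 0.35, 600, (0.05, 0.25, 0.5, 0.2),
                              cfg, muscle="EDL", genotype="WT")
    mko = wt.copy()
    mko["csa_um2"] = scale * mko["csa_um2"]
    mko["genotype"] = "MKO"
    df = pd.concat([wt, mko], ignore_index=True)
    return FixtureSet(
        name="fibre_csa_8wk",
        ground_truth={"percent_reduction": 100.0 * (1.0 - scale)},
        files={"fibres": df},
        params={"n_per_genotype": 600, "paired_scale": scale, "seed": seed},
    )


def paper_fixtures(seed: int = 0) -> dict[str, FixtureSet]:
    """All packaged fixtures, keyed by name.

    Ground truths are calibrated to published reference values; regenerating
    with the same seed is deterministic (noiseless fixtures are seed-free in
    content but record the seed for provenance).
    """
    fixtures = [
        _binding_fixture("ig3_binding", 7.6, seed),
        _binding_fixture("ig34_binding", 4.6, seed + 1),
        _depoly_fixture("depoly_1to2", "1:2", 80.0, seed + 2),
        _depoly_fixture("depoly_1to1", "1:1", 90.0, seed + 3),
        _zline_fixture("zline_8m", 23.0, seed + 4),
        _zline_fixture("zline_12m", 24.0, seed + 5),
        _zline_fixture("zline_24m", 89.0, seed + 6),
        _myotube_fixture(seed + 7),
        _ddct_fixture(seed + 8),
        _fibre_csa_fixture(seed + 9),
    ]
    return {f.name: f for f in fixtures}
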