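"""Actin binding, bundling and pyrene-fluorescence kinetics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fibractin import (
    GeneratorConfig,
    depolymerization_decrease,
    fit_binding_isotherm,
    gen_binding_isotherm,
    gen_depolymerization_pair,
    gen_polymerization_trace,
    normalize_depolymerization,
    normalize_polymerization,
    partition_bundling,
    polymerization_rate,
)
from fibractin.synthetic import binding_fraction


def grid_search_kd(actin_um, bound_frac, lo=0.1, hi=200.0, n=20000):
    """Dense 1-D SSE scan over Kd: the brute-force oracle."""
    kd_grid = np.geomspace(lo, hi, n)
    pred = np.asarray(actin_um)[None, :] / (np.asarray(actin_um)[None, :] + kd_grid[:, None])
    sse = ((pred - np.asarray(bound_frac)) ** 2).sum(axis=1)
    return float(kd_grid[np.argmin(sse)])


class TestBindingFit:
    def test_noiseless_recovery(self):
        df = gen_binding_isotherm(5.0, GeneratorConfig(seed=0))
        fit = fit_binding_isotherm(df["actin_um"], df["bound_frac"])
        assert fit.kd_um == pytest.approx(5.0, rel=1e-6)
        assert not fit.no_binding

    def test_half_saturation_constraint(self):
        # fitted curve must pass through 0.5 at [A] = Kd by construction
        df = gen_binding_isotherm(7.6, GeneratorConfig(seed=1, noise_sd=0.03))
        fit = fit_binding_isotherm(df["actin_um"], df["bound_frac"])
        assert binding_fraction(fit.kd_um, fit.kd_um) == pytest.approx(0.5)

    def test_agrees_with_grid_oracle_on_noisy_data(self):
        for i in range(3):
            df = gen_binding_isotherm(7.6, GeneratorConfig(seed=50 + i, noise_sd=0.05))
            fit = fit_binding_isotherm(df["actin_um"], df["bound_frac"])
            kd_o = grid_search_kd(df["actin_um"], df["bound_frac"])
            assert fit.kd_um == pytest.approx(kd_o, rel=5e-3)

    def test_no_binding_reported_not_fitted(self):
        a = [1, 5, 10, 20, 30]
        fit = fit_binding_isotherm(a, [0.0, 0.01, 0.0, 0.02, 0.01])
        assert fit.no_binding
        assert fit.kd_um is None

    def test_depletion_model_close_to_simple_when_ligand_scarce(self):
        df = gen_binding_isotherm(7.6, GeneratorConfig(seed=2))
        simple = fit_binding_isotherm(df["actin_um"], df["bound_frac"], model="simple")
        depl = fit_binding_isotherm(df["actin_um"], df["bound_frac"],
                                    ligand_um=0.01, model="depletion")
        assert depl.kd_um == pytest.approx(simple.kd_um, rel=1e-3)

    def test_narrow_range_rejected(self):
        with pytest.raises(ValueError, match="5-fold"):
            fit_binding_isotherm([10, 12, 14, 16], [0.5, 0.55, 0.6, 0.62])


class TestBundlingPartition:
    def test_fractions(self):
        p = partition_bundling(30.0, 50.0, 20.0)
        assert (p.bundled_frac, p.filamentous_frac, p.soluble_frac) == (0.3, 0.5, 0.2)

    def test_no_crosslinker_control(self):
        p = partition_bundling(0.0, 70.0, 30.0)
        assert p.bundled_frac == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(
        low=st.floats(0.0, 100.0),
        high=st.floats(0.1, 100.0),
        sup=st.floats(0.0, 100.0),
        k=st.floats(0.1, 50.0),
    )
    def test_sum_to_one_and_scale_invariant(self, low, high, sup, k):
        p = partition_bundling(low, high, sup)
        assert p.bundled_frac + p.filamentous_frac + p.soluble_frac == pytest.approx(1.0, abs=1e-9)
        q = partition_bundling(k * low, k * high, k * sup)
        assert q.bundled_frac == pytest.approx(p.bundled_frac, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            partition_bundling(0.0, 0.0, 0.0)


class TestNormalizePolymerization:
    def trace(self, noise=0.0, seed=0):
        return gen_polymerization_trace(
            0.008, 30.0, 1200.0, 150.0, GeneratorConfig(seed=seed, noise_sd=noise)
        )

    def test_endpoints(self):
        norm = normalize_polymerization(self.trace())
        assert norm["rfu"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert norm["rfu"].iloc[-1] == pytest.approx(1.0, abs=1e-3)

    def test_idempotent(self):
        once = normalize_polymerization(self.trace())
        twice = normalize_polymerization(once)
        assert np.allclose(once["rfu"], twice["rfu"], atol=1e-9)

    def test_affine_invariance(self):
        raw = self.trace()
        shifted = raw.copy()
        shifted["rfu"] = 3.0 * shifted["rfu"] + 500.0
        a = normalize_polymerization(raw)
        b = normalize_polymerization(shifted)
        assert np.allclose(a["rfu"], b["rfu"], atol=1e-12)

    def test_unreached_plateau_rejected(self):
        df = gen_polymerization_trace(
            0.0005, 0.0, 1000.0, 100.0,
            GeneratorConfig(seed=0, grid=tuple(np.arange(0.0, 301.0, 2.0))),
        )
        with pytest.raises(ValueError, match="plateau"):
            normalize_polymerization(df)

    def test_flat_trace_rejected(self):
        df = pd.DataFrame({"time_s": np.arange(20.0), "rfu": np.full(20, 7.0)})
        with pytest.raises(ValueError, match="plateau must exceed baseline"):
            normalize_polymerization(df)


class TestPolymerizationRate:
    def test_rfu_to_nm_conversion(self):
        # piecewise-linear normalized trace with slope 0.002/s through the band
        t = np.arange(0.0, 601.0, 1.0)
        f = np.clip(0.002 * t, 0.0, 1.0)
        res = polymerization_rate(pd.DataFrame({"time_s": t, "rfu": f}), 5.0, 0.1)
        assert res.slope_per_s == pytest.approx(0.002, rel=1e-9)
        assert res.rate == pytest.approx(9.8, rel=1e-9)
        assert res.units == "nM/s"

    def test_rate_scales_with_k_obs(self):
        # short windows: a fast exponential spends little time in the band
        rates = []
        for k in (0.002, 0.004, 0.008):
            raw = gen_polymerization_trace(
                k, 0.0, 1000.0, 100.0,
                GeneratorConfig(seed=0, grid=tuple(np.arange(0.0, 4001.0, 1.0))),
            )
            norm = normalize_polymerization(raw)
            rates.append(polymerization_rate(norm, 5.0, window_frac=0.01).rate)
        assert rates[0] < rates[1] < rates[2]
        assert rates[1] / rates[0] == pytest.approx(2.0, rel=0.1)

    def test_window_inside_band(self):
        raw = gen_polymerization_trace(0.005, 50.0, 900.0, 100.0, GeneratorConfig(seed=0))
        norm = normalize_polymerization(raw)
        res = polymerization_rate(norm, 5.0, window_frac=0.05)
        t = norm["time_s"].to_numpy()
        f = norm["rfu"].to_numpy()
        sel = (t >= res.window[0]) & (t <= res.window[1])
        assert f[sel].min() >= 0.1 and f[sel].max() <= 0.6

    def test_no_linear_band_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        f = np.where(t < 50, 0.0, 1.0)  # jumps straight over the band
        with pytest.raises(ValueError, match="window"):
            polymerization_rate(pd.DataFrame({"time_s": t, "rfu": f}), 5.0)


class TestDepolymerization:
    def make_pair(self, k0=0.01, protection=0.8, noise=0.0, seed=0):
        free, plus = gen_depolymerization_pair(
            k0, protection, GeneratorConfig(seed=seed, noise_sd=noise)
        )
        nfree = normalize_depolymerization(free, 50.0)
        nplus = normalize_depolymerization(plus, 50.0)
        return nfree, nplus

    def test_normalization_convention(self):
        free, _ = gen_depolymerization_pair(0.01, 0.5, GeneratorConfig(seed=0))
        norm = normalize_depolymerization(free, float(free["rfu"].iloc[-1]))
        assert norm["rfu"].iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert norm["rfu"].max() == pytest.approx(1.0, abs=1e-12)

    def test_normalization_inverts_generator(self):
        nfree, nplus = self.make_pair(k0=0.01, protection=0.8)
        t = nfree["time_s"].to_numpy()
        assert np.allclose(nfree["rfu"], np.exp(-0.01 * t), atol=1e-9)
        assert np.allclose(nplus["rfu"], np.exp(-0.002 * t), atol=1e-9)

    def test_identical_traces_zero_decrease(self):
        nfree, _ = self.make_pair()
        res = depolymerization_decrease(nfree, nfree)
        assert res.percent_decrease == pytest.approx(0.0, abs=1e-12)

    def test_half_rate_pair_near_fifty_percent(self):
        """Initial-slope rates for exp(-kt) vs exp(-kt/2) match the analytic
        50% decrease within 2 points when the window is nearly linear."""
        t = np.arange(0.0, 601.0, 1.0)
        k = 0.002
        nfree = pd.DataFrame({"time_s": t, "rfu": np.exp(-k * t)})
        nplus = pd.DataFrame({"time_s": t, "rfu": np.exp(-k / 2 * t)})
        res = depolymerization_decrease(nfree, nplus)
        assert res.percent_decrease == pytest.approx(50.0, abs=2.0)

    def test_exponential_method_recovers_rate_ratio_exactly(self):
        nfree, nplus = self.make_pair(k0=0.01, protection=0.8)
        res = depolymerization_decrease(nfree, nplus, method="exponential")
        assert res.rate_free == pytest.approx(0.01, rel=1e-8)
        assert res.rate_plus == pytest.approx(0.002, rel=1e-8)
        assert res.percent_decrease == pytest.approx(80.0, abs=1e-5)

    def test_time_rescaling_invariance(self):
        nfree, nplus = self.make_pair()
        res_s = depolymerization_decrease(nfree, nplus, window_s=60.0)
        to_min = lambda df: df.assign(time_s=df["time_s"] / 60.0)
        res_min = depolymerization_decrease(to_min(nfree), to_min(nplus), window_s=1.0)
        assert res_min.percent_decrease == pytest.approx(res_s.percent_decrease, rel=1e-9)

    def test_nonpositive_free_rate_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        flat = pd.DataFrame({"time_s": t, "rfu": np.ones_like(t)})
        with pytest.raises(ValueError, match="non-positive"):
            depolymerization_decrease(flat, flat)
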