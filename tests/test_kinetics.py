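"""Digestion kinetics fits and starch fraction accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from beanbolus import datasets, kinetics, synth

TPTS = datasets.INTESTINAL_TIMEPOINTS_MIN


class TestFractionalConversion:
    def test_limits(self):
        assert kinetics.fractional_conversion(0.0, 78.4, 196.4, 0.027) == pytest.approx(78.4)
        assert kinetics.fractional_conversion(1e9, 78.4, 196.4, 0.027) == pytest.approx(196.4)

    def test_worked_value(self):
        # S(60) = 196.4 - 118.0 * exp(-1.62)
        expected = 196.4 - 118.0 * np.exp(-1.62)
        assert kinetics.fractional_conversion(60.0, 78.4, 196.4, 0.027) == pytest.approx(
            expected, abs=1e-9
        )
        assert expected == pytest.approx(173.1, abs=0.1)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            kinetics.fractional_conversion(1.0, 10.0, 20.0, 0.0)
        with pytest.raises(ValueError):
            kinetics.fractional_conversion(1.0, 30.0, 20.0, 0.1)

    @given(st.floats(0.001, 0.1))
    def test_monotone_and_bounded(self, ks):
        t = np.linspace(0, 300, 50)
        s = kinetics.fractional_conversion(t, 50.0, 200.0, ks)
        assert np.all(np.diff(s) > 0)
        assert s.min() >= 50.0 - 1e-9 and s.max() <= 200.0 + 1e-9


class TestFitFractionalConversion:
    @pytest.mark.parametrize(
        "S0,Sf,ks", [(78.4, 196.4, 0.027), (152.3, 324.8, 0.023), (112.5, 209.5, 0.014)]
    )
    def test_noiseless_recovery(self, S0, Sf, ks):
        series = synth.generate_curve(
            synth.CurveSpec("fractional_conversion", (S0, Sf, ks), TPTS)
        )
        fit = kinetics.fit_fractional_conversion(series)
        assert fit.converged
        assert fit.S0 == pytest.approx(S0, rel=0.005)
        assert fit.Sf == pytest.approx(Sf, rel=0.005)
        assert fit.ks == pytest.approx(ks, rel=0.005)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_decreasing_series_rejected(self):
        s = kinetics.DigestaTimeSeries(t=[0, 10, 20, 30], value=[100, 90, 80, 70])
        with pytest.raises(ValueError):
            kinetics.fit_fractional_conversion(s)

    def test_too_few_points(self):
        s = kinetics.DigestaTimeSeries(t=[0, 10, 20], value=[10, 20, 30])
        with pytest.raises(ValueError):
            kinetics.fit_fractional_conversion(s)

    def test_matches_grid_search_oracle(self):
        t = np.array([0.0, 30.0, 60.0, 120.0, 240.0])
        v = kinetics.fractional_conversion(t, 80.0, 200.0, 0.02) + np.array(
            [3.0, -2.0, 1.0, -1.5, 0.5]
        )
        series = kinetics.DigestaTimeSeries(t=t, value=v)
        fit = kinetics.fit_fractional_conversion(series)

        def rss(S0, Sf, ks):
            return float(np.sum((v - (Sf + (S0 - Sf) * np.exp(-ks * t))) ** 2))

        best = (np.inf, None)
        for S0 in np.linspace(70, 95, 40):
            for Sf in np.linspace(185, 215, 40):
                for ks in np.linspace(0.01, 0.035, 40):
                    r = rss(S0, Sf, ks)
                    if r < best[0]:
                        best = (r, (S0, Sf, ks))
        assert rss(fit.S0, fit.Sf, fit.ks) <= best[0] + 1e-9
        for got, grid in zip((fit.S0, fit.Sf, fit.ks), best[1]):
            assert abs(got - grid) <= 2 * abs(grid) * 0.02


class TestFitZeroOrder:
    def test_exact_line(self):
        s = kinetics.DigestaTimeSeries(
            t=TPTS, value=100.0 + 0.1 * np.asarray(TPTS), analyte="serine"
        )
        fit = kinetics.fit_zero_order(s)
        assert fit.P0 == pytest.approx(100.0, abs=1e-9)
        assert fit.kp == pytest.approx(0.1, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_three_point_slope(self):
        s = kinetics.DigestaTimeSeries(t=[0, 10, 20], value=[0.0, 1.0, 2.0], analyte="serine")
        assert kinetics.fit_zero_order(s).kp == pytest.approx(0.1)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kinetics.fit_zero_order(
                kinetics.DigestaTimeSeries(t=[0, 10], value=[0, 1], analyte="serine")
            )

    def test_unbiased_under_noise(self):
        rng = np.random.default_rng(3)
        slopes = []
        for _ in range(300):
            series = synth.generate_curve(
                synth.CurveSpec(
                    "zero_order", (100.0, 0.1), TPTS, noise_sd=2.0,
                    seed=int(rng.integers(2**31)),
                )
            )
            slopes.append(kinetics.fit_zero_order(series).kp)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - 0.1) < 3 * se

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 240, 9))
        v = 50 + 0.2 * t + rng.normal(0, 3, 9)
        fit = kinetics.fit_zero_order(
            kinetics.DigestaTimeSeries(t=t, value=v, analyte="serine")
        )
        xbar, ybar = t.mean(), v.mean()
        slope = float(np.sum((t - xbar) * (v - ybar)) / np.sum((t - xbar) ** 2))
        assert fit.kp == pytest.approx(slope, rel=1e-12)
        assert fit.P0 == pytest.approx(ybar - slope * xbar, rel=1e-12)


class TestStarchFractions:
    def test_conversion_factor(self):
        assert kinetics.GLUCOSE_TO_STARCH == pytest.approx(162.0 / 180.0)
        assert kinetics.GLUCOSE_TO_STARCH == pytest.approx(0.9)

    def test_no_slow_fraction_when_g120_equals_g20(self):
        f = kinetics.starch_fractions(10.0, 10.0, 90.0)
        assert (f.RDS, f.SDS, f.RS) == pytest.approx((10.0, 0.0, 90.0))

    def test_full_digestion_bound(self):
        ts = 75.0
        f = kinetics.starch_fractions(ts / 0.9, ts / 0.9, ts)
        assert f.RDS == pytest.approx(100.0)
        assert f.RS == pytest.approx(0.0, abs=1e-9)

    @given(
        st.floats(0, 50),
        st.floats(0, 50),
        st.floats(100, 300),
    )
    def test_fractions_conserve(self, g20, dg, ts):
        f = kinetics.starch_fractions(g20, g20 + dg, ts)
        assert f.RDS + f.SDS + f.RS == pytest.approx(100.0, abs=1e-9)
        for v in (f.RDS, f.SDS, f.RS):
            assert -1e-9 <= v <= 100 + 1e-9

    @pytest.mark.parametrize(
        "g20,g120,ts", [(10, 5, 100), (-1, 5, 100), (10, 20, 0), (50, 120, 100)]
    )
    def test_precondition_errors(self, g20, g120, ts):
        with pytest.raises(ValueError):
            kinetics.starch_fractions(g20, g120, ts)


class TestGastricEndpoints:
    def test_lookup(self):
        s = kinetics.DigestaTimeSeries(t=[0, 120], value=[12.0, 30.0], phase="gastric")
        assert kinetics.gastric_endpoints(s) == (12.0, 30.0)

    def test_missing_timepoint(self):
        s = kinetics.DigestaTimeSeries(t=[0, 60], value=[12.0, 20.0], phase="gastric")
        with pytest.raises(ValueError):
            kinetics.gastric_endpoints(s)

    def test_generator_roundtrip(self):
        spec = synth.CurveSpec(
            "zero_order", (15.0, 0.1), (0.0, 120.0), phase="gastric", seed=2
        )
        series = synth.generate_curve(spec)
        assert kinetics.gastric_endpoints(series) == (
            series.value[0],
            series.value[1],
        )


class TestDiagnostics:
    def test_perfect_fit(self):
        series = synth.generate_curve(
            synth.CurveSpec("fractional_conversion", (80.0, 200.0, 0.02), TPTS)
        )
        fit = kinetics.fit_fractional_conversion(series)
        diag = kinetics.fit_diagnostics(fit, series)
        assert diag.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(diag.residuals["residual_mg"], 0.0, atol=1e-6)
        assert np.allclose(diag.parity["observed_mg"], diag.parity["predicted_mg"])

    def test_hand_computed_adjusted_r2(self):
        obs = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        pred = np.array([1.2, 2.1, 3.8, 5.2, 6.7])
        ss_res = np.sum((obs - pred) ** 2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        expected = 1 - (1 - (1 - ss_res / ss_tot)) * 4 / 3
        assert kinetics.adjusted_r2(obs, pred, n_params=2) == pytest.approx(expected)

    def test_mean_only_model_r2_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        pred = np.full_like(obs, obs.mean())
        # R^2 = 0 for the mean-only prediction; adjustment pushes it negative
        assert kinetics.adjusted_r2(obs, pred, n_params=2) == pytest.approx(-0.25)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            kinetics.adjusted_r2([1.0, 2.0], [1.0, 2.0], n_params=2)
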