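import numpy as np
import pytest

from smokeitsa.effects import (
    avg_pre_trend,
    avg_trend_change,
    cumulative_effect,
    summarize_effects,
)
from smokeitsa.itsa import MODEL_SPECS, SegmentedPolynomialITS, build_design

from conftest import exact_fit, random_coef

ALL_MODELS = [1, 2, 3, 4, 5]


def _pre_curve(fit):
    """Fitted pre-trend polynomial as a function of the 1-based index T."""
    c = fit.coef_by_name()
    return lambda T: (
        c["const"] + c["T"] * T + c.get("T2", 0.0) * T**2 + c.get("T3", 0.0) * T**3
    )


def _post_curve(fit):
    c = fit.coef_by_name()
    return lambda I: c["X"] + c["XI"] * I + c.get("XI2", 0.0) * I**2


class TestPointEstimates:
    def test_constant_derivative_model1(self):
        fit = exact_fit(1, [10.0, -0.005, 0.0, 0.0])
        assert avg_pre_trend(fit).value == pytest.approx(-0.5, abs=1e-9)

    def test_quadratic_pre_trend_formula(self):
        # mean over T=1..10 of (b1 + 2 b2 T) with b1=0.01, b2=-0.001
        fit = exact_fit(2, [10.0, 0.01, -0.001, 0.0, 0.0])
        expected = 100 * (0.01 - 0.002 * np.mean(np.arange(1, 11)))
        assert avg_pre_trend(fit).value == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-0.1)

    def test_constant_trend_change(self):
        fit = exact_fit(2, [10.0, 0.001, 0.0, 0.0, -0.008])
        assert avg_trend_change(fit, 10).value == pytest.approx(-0.8, abs=1e-9)

    def test_null_trend_change(self):
        fit = exact_fit(1, [10.0, 0.002, 0.0, 0.0])
        assert avg_trend_change(fit, 10).value == pytest.approx(0.0, abs=1e-9)

    def test_cumulative_null(self):
        fit = exact_fit(1, [10.0, 0.002, 0.0, 0.0])
        assert cumulative_effect(fit, 10).value == pytest.approx(0.0, abs=1e-9)

    def test_cumulative_direct_formula(self):
        fit = exact_fit(3, [10.0, 0.0, 0.0, 0.01, -0.02, 0.001])
        assert cumulative_effect(fit, 10).value == pytest.approx(-9.0, abs=1e-8)

    def test_horizon_beyond_window_raises(self):
        fit = exact_fit(1, [10.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="horizon"):
            cumulative_effect(fit, 11)


class TestOracleEquivalence:
    @pytest.mark.parametrize("mid", ALL_MODELS)
    def test_avg_pre_trend_matches_central_difference(self, mid, rng):
        fit = exact_fit(mid, random_coef(mid, rng))
        curve = _pre_curve(fit)
        h = 1e-5
        T_pre = np.arange(1, 11, dtype=float)
        numeric = np.mean((curve(T_pre + h) - curve(T_pre - h)) / (2 * h))
        assert avg_pre_trend(fit).value == pytest.approx(100 * numeric, abs=1e-6)

    @pytest.mark.parametrize("mid", ALL_MODELS)
    def test_avg_trend_change_matches_central_difference(self, mid, rng):
        fit = exact_fit(mid, random_coef(mid, rng))
        curve = _post_curve(fit)
        h = 1e-5
        I = np.arange(0, 11, dtype=float)
        numeric = np.mean((curve(I + h) - curve(I - h)) / (2 * h))
        assert avg_trend_change(fit, 10).value == pytest.approx(100 * numeric, abs=1e-6)

    @pytest.mark.parametrize("mid", ALL_MODELS)
    def test_cumulative_matches_direct_evaluation(self, mid, rng):
        fit = exact_fit(mid, random_coef(mid, rng))
        assert cumulative_effect(fit, 10).value == pytest.approx(
            100 * _post_curve(fit)(10.0), abs=1e-8
        )

    def test_delta_ci_matches_monte_carlo(self, rng):
        # one noisy fixture: percentile CI from coefficient draws out of the
        # HAC covariance should agree with the delta-method interval
        y = 12 - 0.01 * np.arange(1, 22) + rng.normal(0, 0.03, 21)
        fit = SegmentedPolynomialITS(model_id=3).fit(np.arange(-10, 11, dtype=float), y)
        eff = cumulative_effect(fit, 10)
        draws = rng.multivariate_normal(fit.coef_, fit.cov_hac_, size=100_000)
        g = np.zeros(len(fit.coef_))
        for name, wt in (("X", 1.0), ("XI", 10.0), ("XI2", 100.0)):
            if name in fit.feature_names_:
                g[fit.feature_names_.index(name)] = wt
        mc = 100 * draws @ g
        lo, hi = np.percentile(mc, [2.5, 97.5])
        se_mc = mc.std() / np.sqrt(len(mc))
        assert eff.ci_low == pytest.approx(lo, abs=5 * 100 * se_mc + 0.02)
        assert eff.ci_high == pytest.approx(hi, abs=5 * 100 * se_mc + 0.02)


class TestProperties:
    def test_linear_post_consistency(self, rng):
        # for post-degree-1 models the cumulative effect grows linearly:
        # cum(h) - cum(0) = h * (constant trend change)
        fit = exact_fit(2, random_coef(2, rng))
        tc = avg_trend_change(fit, 10).value
        c10 = cumulative_effect(fit, 10).value
        c0 = cumulative_effect(fit, 0).value
        assert c10 - c0 == pytest.approx(10 * tc, abs=1e-8)

    def test_time_origin_is_cosmetic(self, rng):
        # data whose pre-trend polynomial is written in a shifted time
        # variable: the quadratic family absorbs the shift, so the
        # post-break summaries are unchanged and the average pre-trend
        # equals the analytic derivative of the generating curve
        t = np.arange(-10, 11, dtype=float)
        noise = rng.normal(0, 1e-10, 21)
        post_vals = []
        for shift in (0.0, 4.0, -7.0):
            T = np.arange(1, 22, dtype=float) - shift
            I = np.maximum(t, 0.0)
            X = (t >= 0).astype(float)
            y = 10 + 0.01 * T - 0.0005 * T**2 + X * (-0.03 - 0.008 * I) + noise
            fit = SegmentedPolynomialITS(model_id=3).fit(t, y)
            post_vals.append((avg_trend_change(fit, 10).value, cumulative_effect(fit, 10).value))
            T_pre = np.arange(1, 11, dtype=float) - shift
            analytic = 100 * np.mean(0.01 - 0.001 * T_pre)
            assert avg_pre_trend(fit).value == pytest.approx(analytic, abs=1e-6)
        for r in post_vals[1:]:
            np.testing.assert_allclose(r, post_vals[0], atol=1e-7)

    def test_cis_bracket_points(self, rng):
        y = 12 - 0.01 * np.arange(1, 22) + rng.normal(0, 0.05, 21)
        fit = SegmentedPolynomialITS(model_id=2).fit(np.arange(-10, 11, dtype=float), y)
        eff = summarize_effects(fit, "g", "log_smokers")
        for e in (eff.avg_pre_trend, eff.avg_trend_change, eff.cumulative_effect):
            assert e.ci_low <= e.value <= e.ci_high
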