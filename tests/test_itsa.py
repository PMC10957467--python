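from types import SimpleNamespace

import numpy as np
import pytest
import statsmodels.api as sm

from smokeitsa.itsa import (
    MODEL_SPECS,
    ITSAModelSelector,
    SegmentedPolynomialITS,
    build_design,
    newey_west_lags,
    select_model,
)

from conftest import exact_fit, random_coef

T21 = np.arange(-10, 11, dtype=float)


class TestDesign:
    def test_model1_shape(self):
        d = build_design(T21, 1)
        assert d.shape == (21, 4)
        assert list(d.columns) == ["const", "T", "X", "XI"]

    def test_model5_has_all_seven_terms(self):
        d = build_design(T21, 5)
        assert d.shape == (21, 7)
        assert list(d.columns) == ["const", "T", "T2", "T3", "X", "XI", "XI2"]

    @pytest.mark.parametrize("mid,cols", [(1, 4), (2, 5), (3, 6), (4, 6), (5, 7)])
    def test_column_count_matches_degrees(self, mid, cols):
        assert build_design(T21, mid).shape[1] == cols
        assert MODEL_SPECS[mid].n_params == cols

    def test_pre_period_coding(self):
        d = build_design(T21, 5)
        row = d.loc[-3.0]
        assert row["X"] == 0 and row["XI"] == 0 and row["XI2"] == 0

    def test_t0_is_post_by_default(self):
        d = build_design(T21, 1)
        assert d.loc[0.0, "X"] == 1 and d.loc[0.0, "XI"] == 0
        assert d.loc[10.0, "XI"] == 10

    def test_t0_pre_option(self):
        d = build_design(T21, 1, t0_is_post=False)
        assert d.loc[0.0, "X"] == 0
        assert d.loc[1.0, "X"] == 1 and d.loc[1.0, "XI"] == 0

    def test_time_index_is_one_based_increasing(self):
        d = build_design(T21, 1)
        np.testing.assert_array_equal(d["T"], np.arange(1, 22))

    def test_unknown_model_id(self):
        with pytest.raises(ValueError, match="model_id"):
            build_design(T21, 7)


class TestFit:
    def test_exact_linear_interpolation(self):
        t = T21
        y = 2.0 + 0.1 * np.arange(1, 22)
        fit = SegmentedPolynomialITS(model_id=1).fit(t, y)
        assert fit.coef_by_name()["T"] == pytest.approx(0.1, abs=1e-12)
        np.testing.assert_allclose(fit.resid_, 0, atol=1e-12)

    def test_coefficients_invariant_to_hac_lags(self, rng):
        y = rng.normal(10, 0.1, 21)
        fits = [SegmentedPolynomialITS(3, hac_lags=L).fit(T21, y) for L in (0, 2, 5)]
        for f in fits[1:]:
            np.testing.assert_allclose(f.coef_, fits[0].coef_, rtol=1e-14)

    @pytest.mark.parametrize("degree, mid", [(1, 1), (2, 3), (3, 5)])
    def test_no_break_polynomial_has_zero_post_terms(self, degree, mid):
        T = np.arange(1, 22, dtype=float)
        y = 10 - 0.01 * T + 0.002 * T**2 - 0.0001 * T**3 * (degree >= 3)
        if degree < 2:
            y = 10 - 0.01 * T
        fit = SegmentedPolynomialITS(model_id=mid).fit(T21, y)
        for name, val in fit.coef_by_name().items():
            if name.startswith("X"):
                assert val == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("mid", [1, 2, 3, 4, 5])
    def test_matches_normal_equations_oracle(self, mid, rng):
        y = rng.normal(10, 0.5, 21)
        fit = SegmentedPolynomialITS(model_id=mid).fit(T21, y)
        M = build_design(T21, mid).to_numpy()
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        np.testing.assert_allclose(fit.coef_, beta, rtol=1e-10)

    def test_rank_deficient_design_raises(self):
        # constant event time makes X and XI collinear with the intercept
        with pytest.raises(np.linalg.LinAlgError):
            SegmentedPolynomialITS(model_id=1).fit(np.repeat(5.0, 21), np.ones(21))

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="observations"):
            SegmentedPolynomialITS(model_id=5).fit(np.arange(-3, 3, dtype=float), np.ones(6))

    def test_nonfinite_outcome_rejected(self):
        y = np.ones(21)
        y[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            SegmentedPolynomialITS(model_id=1).fit(T21, y)

    def test_automatic_lag_rule(self):
        assert newey_west_lags(21) == 2
        assert newey_west_lags(100) == 4
        fit = SegmentedPolynomialITS(model_id=1).fit(T21, np.linspace(1, 2, 21))
        assert fit.hac_lags_ == 2


class TestHAC:
    @pytest.mark.parametrize("mid", [1, 3, 5])
    @pytest.mark.parametrize("lags", [0, 2, 4])
    def test_matches_statsmodels_hac(self, mid, lags, rng):
        y = 10 - 0.01 * np.arange(1, 22) + rng.normal(0, 0.05, 21)
        fit = SegmentedPolynomialITS(model_id=mid, hac_lags=lags).fit(T21, y)
        X = build_design(T21, mid).to_numpy()
        res = sm.OLS(y, X).fit(cov_type="HAC", cov_kwds={"maxlags": lags, "use_correction": False})
        ref = np.asarray(res.cov_params())
        np.testing.assert_allclose(fit.cov_hac_, ref, rtol=1e-7, atol=1e-9 * np.abs(ref).max())

    def test_zero_lags_equals_white_sandwich(self, rng):
        y = rng.normal(5, 0.3, 21)
        fit = SegmentedPolynomialITS(model_id=2, hac_lags=0).fit(T21, y)
        X = build_design(T21, 2).to_numpy()
        u = y - X @ fit.coef_
        bread = np.linalg.inv(X.T @ X)
        white = bread @ (X * u[:, None] ** 2).T @ X @ bread
        np.testing.assert_allclose(fit.cov_hac_, white, rtol=1e-10)

    def test_covariance_symmetric_psd(self, rng):
        y = rng.normal(0, 1, 21)
        fit = SegmentedPolynomialITS(model_id=4, hac_lags=2).fit(T21, y)
        np.testing.assert_allclose(fit.cov_hac_, fit.cov_hac_.T, atol=1e-14)
        assert np.all(np.linalg.eigvalsh(fit.cov_hac_) > -1e-10)


class TestSelection:
    def test_single_candidate_returned_unchanged(self):
        fit = exact_fit(2, [10, 0.01, -0.001, -0.05, -0.01])
        assert select_model([fit]) is fit

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError, match="no fitted"):
            select_model([])

    def test_tie_breaks_to_smaller_model_id(self):
        a = SimpleNamespace(aic_=-100.0, aic_pre_=-50.0, model_id=3)
        b = SimpleNamespace(aic_=-100.0, aic_pre_=-50.0, model_id=2)
        assert select_model([a, b]).model_id == 2

    def test_selector_prefers_true_quadratic(self, rng):
        # data with a genuine quadratic pre-trend and low noise: the
        # quadratic-pre specifications (2 or 3) should win a majority
        wins = 0
        n_trials = 200
        T = np.arange(1, 22, dtype=float)
        for _ in range(n_trials):
            y = 10 + 0.05 * T - 0.003 * T**2 + rng.normal(0, 0.01, 21)
            sel = ITSAModelSelector().fit(T21, y)
            wins += sel.best_model_id_ in (2, 3)
        assert wins > n_trials / 2

    def test_selector_exposes_fitted_attributes(self):
        y = np.linspace(12, 11, 21)
        sel = ITSAModelSelector().fit(T21, y)
        assert set(sel.aics_) == {1, 2, 3, 4, 5}
        assert sel.best_estimator_ is sel.estimators_[sel.best_model_id_]
        np.testing.assert_allclose(sel.predict(T21), y, atol=1e-9)

    def test_sklearn_params_round_trip(self):
        est = SegmentedPolynomialITS(model_id=3, hac_lags=4)
        clone_params = est.get_params()
        est2 = SegmentedPolynomialITS(**clone_params)
        assert est2.model_id == 3 and est2.hac_lags == 4
        sel = ITSAModelSelector(aic_window="pre")
        assert sel.get_params()["aic_window"] == "pre"
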