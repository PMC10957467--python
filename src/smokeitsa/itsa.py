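"""Segmented polynomial interrupted time-series regression.

An interrupted time series (ITS) regresses an outcome observed at regular
event times around an intervention on a secular polynomial trend plus terms
that switch on at the intervention: a level shift and a (possibly quadratic)
change in slope.  Five fixed specifications are supported, indexed by
``model_id``::

    1:  y = b0 + b1*T                   + b4*X + b5*X*I
    2:  y = b0 + b1*T + b2*T^2          + b4*X + b5*X*I
    3:  y = b0 + b1*T + b2*T^2          + b4*X + b5*X*I + b6*X*I^2
    4:  y = b0 + b1*T + b2*T^2 + b3*T^3 + b4*X + b5*X*I
    5:  y = b0 + b1*T + b2*T^2 + b3*T^3 + b4*X + b5*X*I + b6*X*I^2

where T is a 1-based time index over the analysis window, X is the
post-intervention indicator and I counts years since the intervention
(0 before it).  Estimation is ordinary least squares; inference uses the
Newey-West heteroskedasticity-and-autocorrelation-consistent (HAC)
covariance with Bartlett-kernel weights.  Candidate specifications are
compared by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "MODEL_SPECS",
    "ModelSpec",
    "build_design",
    "newey_west_lags",
    "SegmentedPolynomialITS",
    "ITSAModelSelector",
    "fit_ols_hac",
    "select_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """One of the five segmented polynomial specifications.

    ``pre_degree`` is the degree of the secular polynomial in T;
    ``post_degree`` counts the post-intervention trend terms in I beyond
    the level shift (1 = slope change only, 2 = slope + quadratic).
    """

    model_id: int
    pre_degree: int
    post_degree: int

    @property
    def n_params(self) -> int:
        # intercept + pre polynomial + level shift + post trend terms
        return 2 + self.pre_degree + self.post_degree

    def column_names(self) -> list[str]:
        names = ["const"] + [f"T{p}" if p > 1 else "T" for p in range(1, self.pre_degree + 1)]
        names.append("X")
        names += [f"XI{p}" if p > 1 else "XI" for p in range(1, self.post_degree + 1)]
        return names


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, 1, 1),
    2: ModelSpec(2, 2, 1),
    3: ModelSpec(3, 2, 2),
    4: ModelSpec(4, 3, 1),
    5: ModelSpec(5, 3, 2),
}


def _event_time_vector(event_time) -> np.ndarray:
    t = np.asarray(event_time, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("event_time must be a 1-d sequence (or a single-column array)")
    return t


def build_design(event_time, model_id: int, *, t0_is_post: bool = True) -> pd.DataFrame:
    """Build the regressor matrix for one specification.

    Parameters
    ----------
    event_time
        Years relative to the intervention (t = 0 at the intervention year),
        in window order.
    model_id
        Specification id in 1..5.
    t0_is_post
        Whether the intervention year itself belongs to the post period
        (X = 1, I = 0 at t = 0).  If False, t = 0 is treated as pre.

    Returns
    -------
    DataFrame with one row per event time and named coefficient columns.
    T is the 1-based window index, X the post indicator, I years since the
    intervention (clamped at 0 before it).
    """
    if model_id not in MODEL_SPECS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of 1..5")
    spec = MODEL_SPECS[model_id]
    t = _event_time_vector(event_time)
    if len(t) < spec.n_params + 1:
        raise ValueError(
            f"model {model_id} needs at least {spec.n_params + 1} observations, got {len(t)}"
        )
    T = np.arange(1, len(t) + 1, dtype=float)
    post = t >= 0 if t0_is_post else t > 0
    X = post.astype(float)
    I = np.where(post, t - (0.0 if t0_is_post else 1.0), 0.0)
    # with t0 pre, the first post year gets I = 0 so the level shift and
    # slope-change terms keep the same interpretation
    cols: dict[str, np.ndarray] = {"const": np.ones_like(T)}
    for p in range(1, spec.pre_degree + 1):
        cols["T" if p == 1 else f"T{p}"] = T**p
    cols["X"] = X
    for p in range(1, spec.post_degree + 1):
        cols["XI" if p == 1 else f"XI{p}"] = X * I**p
    return pd.DataFrame(cols, index=np.asarray(event_time))


def newey_west_lags(n_obs: int) -> int:
    """Automatic Bartlett truncation lag, floor(4 * (n/100)^(2/9))."""
    return int(np.floor(4.0 * (n_obs / 100.0) ** (2.0 / 9.0)))


def _hac_covariance(X: np.ndarray, resid: np.ndarray, lags: int) -> np.ndarray:
    """Newey-West covariance of OLS coefficients, Bartlett kernel, no
    small-sample correction (lag-wise accumulation form)."""
    n = X.shape[0]
    xu = X * resid[:, None]
    S = xu.T @ xu  # lag-0 (White) meat
    for lag in range(1, lags + 1):
        w = 1.0 - lag / (lags + 1.0)
        gamma = xu[lag:].T @ xu[:-lag]
        S += w * (gamma + gamma.T)
    bread = np.linalg.inv(X.T @ X)
    return bread @ S @ bread


class SegmentedPolynomialITS(RegressorMixin, BaseEstimator):
    """One segmented polynomial ITS specification fit by OLS with HAC errors.

    Parameters
    ----------
    model_id : int, default 1
        Which of the five specifications to fit.
    hac_lags : int or None, default None
        Bartlett truncation lag for the Newey-West covariance; ``None``
        selects ``floor(4 * (n/100)^(2/9))`` (2 for the standard 21-point
        window).
    t0_is_post : bool, default True
        Assign the intervention year itself to the post period.

    Attributes
    ----------
    coef_ : ndarray
        OLS coefficients in design-column order.
    feature_names_ : list of str
        Design column names ("const", "T", ..., "X", "XI", "XI2").
    cov_hac_ : ndarray
        Newey-West covariance of ``coef_``.
    aic_ : float
        ``n*log(RSS/n) + 2k`` on the fitted window.
    aic_pre_ : float
        Same formula restricted to pre-intervention residuals (with k of the
        full model); an alternative selection criterion.
    resid_ : ndarray
        Per-observation residuals.
    """

    def __init__(self, model_id: int = 1, hac_lags: int | None = None, t0_is_post: bool = True):
        self.model_id = model_id
        self.hac_lags = hac_lags
        self.t0_is_post = t0_is_post

    def fit(self, X, y):
        """Fit to an outcome series.

        ``X`` is the event-time vector (years relative to the intervention,
        shape (n,) or (n, 1)); ``y`` the outcome (log scale in the intended
        application).
        """
        t = _event_time_vector(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError(f"X and y lengths differ: {t.shape} vs {y.shape}")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        design = build_design(t, self.model_id, t0_is_post=self.t0_is_post)
        M = design.to_numpy()
        n, k = M.shape
        if np.linalg.matrix_rank(M) < k:
            raise np.linalg.LinAlgError(
                f"design matrix for model {self.model_id} is rank deficient (n={n})"
            )
        coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
        resid = y - M @ coef
        rss = float(resid @ resid)
        lags = self.hac_lags if self.hac_lags is not None else newey_west_lags(n)

        self.spec_ = MODEL_SPECS[self.model_id]
        self.feature_names_ = list(design.columns)
        self.event_time_ = t
        self.coef_ = coef
        self.resid_ = resid
        self.rss_ = rss
        self.nobs_ = n
        self.hac_lags_ = lags
        self.cov_hac_ = _hac_covariance(M, resid, lags)
        self.aic_ = n * np.log(max(rss, 1e-300) / n) + 2 * k
        pre = ~(t >= 0 if self.t0_is_post else t > 0)
        rss_pre = float(resid[pre] @ resid[pre])
        n_pre = int(pre.sum())
        self.aic_pre_ = n_pre * np.log(max(rss_pre, 1e-300) / n_pre) + 2 * k
        return self

    # -- prediction -----------------------------------------------------

    def _design(self, event_time) -> np.ndarray:
        return build_design(event_time, self.model_id, t0_is_post=self.t0_is_post).to_numpy()

    def predict(self, X):
        """Fitted outcome at the given event times (full model, break included)."""
        self._check_fitted()
        t = _event_time_vector(X)
        if len(t) != self.nobs_ or not np.allclose(t, self.event_time_):
            raise ValueError(
                "predict is only defined on the fitted window: the 1-based time "
                "index T is anchored to the window used in fit"
            )
        return self._design(t) @ self.coef_

    def predict_pretrend(self, X):
        """Secular-trend-only prediction (b0 + b1*T + ... with break terms zeroed).

        Evaluated at any subset of the fitted window; this is the
        counterfactual continuation of the pre-intervention trend.
        """
        self._check_fitted()
        t = _event_time_vector(X)
        full = build_design(self.event_time_, self.model_id, t0_is_post=self.t0_is_post)
        mask = np.isin(self.event_time_, t)
        if mask.sum() != len(t):
            raise ValueError("requested event times fall outside the fitted window")
        M = full.to_numpy()[mask]
        coef_pre = self.coef_.copy()
        for i, name in enumerate(self.feature_names_):
            if name.startswith("X"):
                coef_pre[i] = 0.0
        return M @ coef_pre

    def coef_by_name(self) -> dict[str, float]:
        self._check_fitted()
        return dict(zip(self.feature_names_, self.coef_))

    def hac_se(self) -> np.ndarray:
        """HAC standard errors of the coefficients."""
        self._check_fitted()
        return np.sqrt(np.diag(self.cov_hac_))

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise AttributeError("estimator is not fitted; call fit(X, y) first")


class ITSAModelSelector(RegressorMixin, BaseEstimator):
    """Fit all five segmented specifications and keep the AIC-best one.

    Parameters
    ----------
    hac_lags, t0_is_post
        Passed to each :class:`SegmentedPolynomialITS` candidate.
    aic_window : {"full", "pre"}, default "full"
        Compare candidates on the full-window AIC or on the AIC of the
        pre-intervention residuals only.
    candidates : sequence of int, default (1, 2, 3, 4, 5)
        Model ids to consider.

    Attributes
    ----------
    best_model_id_ : int
    best_estimator_ : SegmentedPolynomialITS
    aics_ : dict mapping model_id -> comparison AIC
    estimators_ : dict mapping model_id -> fitted candidate
    """

    def __init__(
        self,
        hac_lags: int | None = None,
        t0_is_post: bool = True,
        aic_window: str = "full",
        candidates: tuple[int, ...] = (1, 2, 3, 4, 5),
    ):
        self.hac_lags = hac_lags
        self.t0_is_post = t0_is_post
        self.aic_window = aic_window
        self.candidates = candidates

    def fit(self, X, y):
        if len(self.candidates) == 0:
            raise ValueError("no candidate models supplied")
        if self.aic_window not in ("full", "pre"):
            raise ValueError(f"aic_window must be 'full' or 'pre', got {self.aic_window!r}")
        self.estimators_ = {}
        self.aics_ = {}
        for mid in self.candidates:
            est = SegmentedPolynomialITS(
                model_id=mid, hac_lags=self.hac_lags, t0_is_post=self.t0_is_post
            ).fit(X, y)
            self.estimators_[mid] = est
            self.aics_[mid] = est.aic_ if self.aic_window == "full" else est.aic_pre_
        # ties break toward the smaller model_id (fewer parameters first)
        self.best_model_id_ = min(sorted(self.aics_), key=lambda m: self.aics_[m])
        self.best_estimator_ = self.estimators_[self.best_model_id_]
        return self

    def predict(self, X):
        return self.best_estimator_.predict(X)


# -- thin functional wrappers ------------------------------------------


def fit_ols_hac(
    event_time, y, model_id: int = 1, hac_lags: int | None = None, t0_is_post: bool = True
) -> SegmentedPolynomialITS:
    """Fit one specification; functional form of :class:`SegmentedPolynomialITS`."""
    return SegmentedPolynomialITS(model_id=model_id, hac_lags=hac_lags, t0_is_post=t0_is_post).fit(
        event_time, y
    )


def select_model(fits: list[SegmentedPolynomialITS], aic_window: str = "full") -> SegmentedPolynomialITS:
    """Return the minimum-AIC fit; ties go to the smallest model_id."""
    if not fits:
        raise ValueError("no fitted models to select from")
    key = (lambda f: (f.aic_, f.model_id)) if aic_window == "full" else (lambda f: (f.aic_pre_, f.model_id))
    return min(sorted(fits, key=lambda f: f.model_id), key=key)
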