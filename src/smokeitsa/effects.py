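"""Marginal and cumulative intervention effects from a fitted ITS model.

Because the outcomes are modeled on the log scale, coefficients are relative
changes: a trend derivative of -0.008 log-points/year is reported as
-0.8% per year.  Three summaries are produced from a fitted
:class:`~smokeitsa.itsa.SegmentedPolynomialITS`:

* average pre-intervention trend: the mean over pre-period years of
  d/dT (b1*T + b2*T^2 + b3*T^3);
* average change in trend after the intervention: the mean over
  post-period years of d/dI (b5*I + b6*I^2);
* cumulative effect at a horizon h: b4 + b5*h + b6*h^2, the gap at year h
  between the fitted post trajectory and the continued pre trend.

All three are linear in the coefficients, so delta-method confidence
intervals on the HAC covariance are exact (no curvature term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .itsa import SegmentedPolynomialITS

__all__ = [
    "EffectEstimate",
    "EffectEstimates",
    "avg_pre_trend",
    "avg_trend_change",
    "cumulative_effect",
    "relative_percent",
    "summarize_effects",
]


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate (percent scale) with a 95% CI and its gradient."""

    value: float
    ci_low: float
    ci_high: float
    se: float

    def as_tuple(self) -> tuple[float, float, float]:
        return self.value, self.ci_low, self.ci_high


@dataclass
class EffectEstimates:
    """Per group x outcome bundle of the three reported effect summaries."""

    group: str
    outcome: str
    model_id: int
    horizon: int
    avg_pre_trend: EffectEstimate
    avg_trend_change: EffectEstimate
    cumulative_effect: EffectEstimate
    extra: dict = field(default_factory=dict)


def relative_percent(log_points: float) -> float:
    """Exact relative change in percent, (e^x - 1)*100, for a log-point x.

    The default reporting convention is 100x log-points; this helper is the
    exact transformation used when converting effects to counts.
    """
    return float(np.expm1(log_points) * 100.0)


def _linear_effect(
    fit: SegmentedPolynomialITS, gradient: np.ndarray, ci_level: float = 0.95
) -> EffectEstimate:
    """Point estimate and normal CI of 100 * (gradient . beta)."""
    est = float(gradient @ fit.coef_)
    var = float(gradient @ fit.cov_hac_ @ gradient)
    se = np.sqrt(max(var, 0.0))
    z = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    return EffectEstimate(
        value=100.0 * est,
        ci_low=100.0 * (est - z * se),
        ci_high=100.0 * (est + z * se),
        se=100.0 * se,
    )


def _coef_index(fit: SegmentedPolynomialITS, name: str) -> int | None:
    try:
        return fit.feature_names_.index(name)
    except ValueError:
        return None


def avg_pre_trend(fit: SegmentedPolynomialITS, ci_level: float = 0.95) -> EffectEstimate:
    """Average annual trend (%/yr) over the pre-intervention period.

    Mean over pre-period rows of the derivative of the secular polynomial
    with respect to the window time index T.
    """
    t = fit.event_time_
    pre = ~(t >= 0 if fit.t0_is_post else t > 0)
    T = np.arange(1, fit.nobs_ + 1, dtype=float)[pre]
    g = np.zeros_like(fit.coef_)
    for power, name in ((1, "T"), (2, "T2"), (3, "T3")):
        idx = _coef_index(fit, name)
        if idx is not None:
            g[idx] = np.mean(power * T ** (power - 1))
    return _linear_effect(fit, g, ci_level)


def avg_trend_change(
    fit: SegmentedPolynomialITS,
    horizon: int | None = None,
    ci_level: float = 0.95,
    grid_from_zero: bool = True,
) -> EffectEstimate:
    """Average annual change in trend (%/yr) after the intervention.

    Mean over the post-period grid I = 0..h (or 1..h when
    ``grid_from_zero=False``) of the derivative of the post terms with
    respect to I.
    """
    if horizon is None:
        horizon = int(fit.event_time_.max())
    start = 0 if grid_from_zero else 1
    I = np.arange(start, horizon + 1, dtype=float)
    g = np.zeros_like(fit.coef_)
    for power, name in ((1, "XI"), (2, "XI2")):
        idx = _coef_index(fit, name)
        if idx is not None:
            g[idx] = np.mean(power * I ** (power - 1))
    return _linear_effect(fit, g, ci_level)


def cumulative_effect(
    fit: SegmentedPolynomialITS, horizon: int = 10, ci_level: float = 0.95
) -> EffectEstimate:
    """Cumulative effect (%) at ``horizon`` years after the intervention.

    The level shift plus the accumulated slope change, b4 + b5*h + b6*h^2,
    i.e. the log-scale gap between the fitted post-period trajectory and
    the counterfactual pre-trend at I = h.
    """
    max_I = int(fit.event_time_.max() - (0 if fit.t0_is_post else 1))
    if horizon > max_I:
        raise ValueError(f"horizon {horizon} exceeds the post window (max I = {max_I})")
    g = np.zeros_like(fit.coef_)
    for name, weight in (("X", 1.0), ("XI", float(horizon)), ("XI2", float(horizon) ** 2)):
        idx = _coef_index(fit, name)
        if idx is not None:
            g[idx] = weight
    return _linear_effect(fit, g, ci_level)


def summarize_effects(
    fit: SegmentedPolynomialITS,
    group: str,
    outcome: str,
    horizon: int = 10,
    ci_level: float = 0.95,
) -> EffectEstimates:
    """The three effect summaries for one group x outcome fit."""
    return EffectEstimates(
        group=group,
        outcome=outcome,
        model_id=fit.model_id,
        horizon=horizon,
        avg_pre_trend=avg_pre_trend(fit, ci_level),
        avg_trend_change=avg_trend_change(fit, horizon, ci_level),
        cumulative_effect=cumulative_effect(fit, horizon, ci_level),
    )
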