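"""Synthetic country panels with known ground truth.

Each simulated country carries an annual log-count trajectory for young
(10-24) current smokers — a polynomial secular trend in event time plus a
level/slope/quadratic break switching on at the country's ratification
year — with stationary AR(1) Gaussian noise on the log scale
(multiplicative counts), a smoothly growing population denominator, and a
45-59 former/ever pair whose quit ratio drifts upward after ratification.

Ground truth for any country group is defined by applying the effect
formulas to the noiseless aggregate curves (the log of summed counts with
and without the break), which coincides with the closed-form break
coefficients whenever countries share them.  Scenario presets mirror the
study conditions: ratification years sampled over 2004-2010 with median
2005, baseline prevalences 8-25%, trend changes within a few percent per
year, and a high-tax-change subgroup with roughly double-sized effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import WindowConfig
from .itsa import SegmentedPolynomialITS
from . import effects as _effects
from .panel_io import AGE_OLD, AGE_YOUNG

__all__ = [
    "SimCountryParams",
    "SimTruth",
    "SimulatedCohort",
    "simulate_country",
    "simulate_cohort",
    "truth_closed_form",
    "truth_from_noiseless_curves",
    "RATIFICATION_YEAR_PMF",
    "PRESETS",
]

# ratification years 2004..2010, median 2005
RATIFICATION_YEAR_PMF = {
    2004: 0.40,
    2005: 0.20,
    2006: 0.12,
    2007: 0.10,
    2008: 0.08,
    2009: 0.06,
    2010: 0.04,
}


@dataclass(frozen=True)
class SimCountryParams:
    """Generative parameters for one country.

    The young-smoker log count at event time t (years since ratification) is

        b0 + b1*t + b2*t^2 + b3*t^3 + X(t)*(level + slope*I + quad*I^2) + e(t)

    with X(t) = 1 for t >= 0, I = max(t, 0), and e an AR(1) process with
    stationary standard deviation ``noise_sd`` and lag-1 correlation
    ``ar1_rho``.  The quit ratio at 45-59 follows
    q0 * exp(quit_pre_trend * t + quit_drift * I) with its own noise.
    """

    country_id: str
    ratification_year: int = 2005
    baseline_log_smokers: float = np.log(5e5)
    pre_trend: tuple[float, float, float] = (-0.02, 0.0, 0.0)
    level_change: float = 0.0  # log-points at t = 0
    slope_change: float = 0.0  # log-points / yr
    quad_change: float = 0.0  # log-points / yr^2
    noise_sd: float = 0.02
    ar1_rho: float = 0.5
    baseline_prevalence: float = 0.15
    pop_growth: float = 0.01
    baseline_quit_ratio: float = 0.34
    quit_pre_trend: float = 0.0
    quit_drift: float = 0.002
    quit_noise_sd: float = 0.005
    ever_share_45_59: float = 0.5  # ever smokers as a share of 45-59 population
    income_group: str = "upper-middle"
    tax_change_pp: float | None = 2.0
    survey_years_count: int = 12

    def __post_init__(self):
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in [0, 1) for stationary noise")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        if not 0 < self.baseline_quit_ratio <= 1:
            raise ValueError("baseline_quit_ratio must be in (0, 1]")

    def log_smokers(self, event_time: np.ndarray, with_break: bool = True) -> np.ndarray:
        """Noiseless log young-smoker count at the given event times."""
        t = np.asarray(event_time, dtype=float)
        b1, b2, b3 = self.pre_trend
        y = self.baseline_log_smokers + b1 * t + b2 * t**2 + b3 * t**3
        if with_break:
            I = np.maximum(t, 0.0)
            X = (t >= 0).astype(float)
            y = y + X * (self.level_change + self.slope_change * I + self.quad_change * I**2)
        return y

    def log_quit_ratio(self, event_time: np.ndarray, with_break: bool = True) -> np.ndarray:
        t = np.asarray(event_time, dtype=float)
        q = np.log(self.baseline_quit_ratio) + self.quit_pre_trend * t
        if with_break:
            q = q + np.maximum(t, 0.0) * self.quit_drift
        return q


@dataclass
class SimTruth:
    """Per-group ground-truth effect summaries at the stated horizon."""

    horizon: int
    groups: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    """Generator output: the three input tables plus ground truth."""

    panel: pd.DataFrame  # canonical panel_io columns
    meta: pd.DataFrame  # CSV-ready meta table (default schema names)
    params: dict[str, SimCountryParams]
    group_members: dict[str, list[str]]
    truth: SimTruth


def _ar1(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        e[i] = rho * e[i - 1] + rng.normal(0.0, innov_sd)
    return e


def simulate_country(
    params: SimCountryParams,
    years: range = range(1994, 2021),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one country's long panel rows over the given calendar years.

    Returns canonical panel columns (both age bands); counts are rounded to
    whole persons.  Raises if the noiseless implied prevalence leaves (0, 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yrs = np.asarray(list(years))
    t = yrs - params.ratification_year
    n = len(yrs)

    log_sm = params.log_smokers(t) + _ar1(rng, n, params.noise_sd, params.ar1_rho)
    smokers = np.exp(log_sm)
    pop0 = np.exp(params.baseline_log_smokers) / params.baseline_prevalence
    pop_young = pop0 * (1.0 + params.pop_growth) ** t.astype(float)
    prev_noiseless = np.exp(params.log_smokers(t)) / pop_young
    if np.any(prev_noiseless >= 1.0) or np.any(prev_noiseless <= 0.0):
        raise ValueError(
            f"{params.country_id}: implied noiseless prevalence leaves (0,1); "
            f"range {prev_noiseless.min():.3g}..{prev_noiseless.max():.3g}"
        )
    smokers = np.minimum(smokers, pop_young)  # noise guard; inactive at sane params

    pop_old = 0.8 * pop_young
    ever = params.ever_share_45_59 * pop_old
    log_q = params.log_quit_ratio(t) + _ar1(rng, n, params.quit_noise_sd, params.ar1_rho)
    q = np.exp(log_q)
    if np.any(np.exp(params.log_quit_ratio(t)) >= 1.0):
        raise ValueError(f"{params.country_id}: noiseless quit ratio reaches 1")
    former = np.minimum(q, 0.999) * ever
    current_old = ever - former

    young = pd.DataFrame(
        {
            "country_id": params.country_id,
            "year": yrs,
            "age_band": AGE_YOUNG,
            "current_smokers": np.round(smokers),
            "population": np.round(pop_young),
            "former_smokers": 0.0,
            "ever_smokers": 0.0,
        }
    )
    old = pd.DataFrame(
        {
            "country_id": params.country_id,
            "year": yrs,
            "age_band": AGE_OLD,
            "current_smokers": np.round(current_old),
            "population": np.round(pop_old),
            "former_smokers": np.round(former),
            "ever_smokers": np.round(ever),
        }
    )
    out = pd.concat([young, old], ignore_index=True)
    out.loc[out["age_band"] == AGE_OLD, "former_smokers"] = np.minimum(
        out.loc[out["age_band"] == AGE_OLD, "former_smokers"],
        out.loc[out["age_band"] == AGE_OLD, "ever_smokers"],
    )
    return out


# -- ground truth -------------------------------------------------------


def truth_closed_form(
    params_list: list[SimCountryParams], horizon: int = 10
) -> dict[str, float]:
    """Closed-form group truth; valid when members share break parameters."""
    p0 = params_list[0]
    for p in params_list[1:]:
        if (p.level_change, p.slope_change, p.quad_change) != (
            p0.level_change,
            p0.slope_change,
            p0.quad_change,
        ):
            raise ValueError("closed form requires identical break parameters across members")
    I = np.arange(0, horizon + 1, dtype=float)
    trend_change = np.mean(p0.slope_change + 2.0 * p0.quad_change * I)
    cum = p0.level_change + p0.slope_change * horizon + p0.quad_change * horizon**2
    t = np.arange(0, horizon + 1)
    with_b = np.sum([np.exp(p.log_smokers(t, True)) for p in params_list], axis=0)
    without = np.sum([np.exp(p.log_smokers(t, False)) for p in params_list], axis=0)
    return {
        "avg_trend_change_pct": 100.0 * trend_change,
        "cumulative_effect_pct": 100.0 * cum,
        "averted_count": float(without[-1] - with_b[-1]),
        "quit_cumulative_pct": 100.0 * p0.quit_drift * horizon,
    }


def truth_from_noiseless_curves(
    params_list: list[SimCountryParams],
    window: WindowConfig = WindowConfig(),
    horizon: int = 10,
) -> dict[str, float]:
    """Group truth from the noiseless aggregate curves.

    Aggregates unrounded noiseless member counts, fits the most general
    specification (exact on polynomial data), and reads the truth off the
    same effect formulas the analysis uses; the averted count compares the
    aggregate curves with and without the break directly.
    """
    t = window.event_times().astype(float)
    with_b = np.sum([np.exp(p.log_smokers(t, True)) for p in params_list], axis=0)
    without = np.sum([np.exp(p.log_smokers(t, False)) for p in params_list], axis=0)
    fit = SegmentedPolynomialITS(model_id=5, hac_lags=0).fit(t, np.log(with_b))
    trend_change = _effects.avg_trend_change(fit, horizon).value
    cum = _effects.cumulative_effect(fit, horizon).value

    def ever_counts(p: SimCountryParams) -> np.ndarray:
        pop0 = np.exp(p.baseline_log_smokers) / p.baseline_prevalence
        return p.ever_share_45_59 * 0.8 * pop0 * (1.0 + p.pop_growth) ** t

    # aggregate former counts with/without the cessation break (shared ever
    # denominator cancels in the log quit-ratio difference)
    q_with = np.sum(
        [ever_counts(p) * np.exp(p.log_quit_ratio(t, True)) for p in params_list], axis=0
    )
    q_without = np.sum(
        [ever_counts(p) * np.exp(p.log_quit_ratio(t, False)) for p in params_list], axis=0
    )
    h_idx = int(np.searchsorted(t, horizon))
    quit_cum = 100.0 * (np.log(q_with[h_idx]) - np.log(q_without[h_idx]))
    i0 = int(np.searchsorted(t, 0))
    return {
        "avg_trend_change_pct": trend_change,
        "cumulative_effect_pct": cum,
        "averted_count": float(without[i0 + horizon] - with_b[i0 + horizon]),
        "quit_cumulative_pct": quit_cum,
    }


# -- cohort-level scenarios ---------------------------------------------

# effect profiles in log-points: (level, slope, quad, quit_drift); the world
# profile accumulates to -15% at a 10-year horizon, the null to 0
PRESETS: dict[str, dict] = {
    "world": {"effect": (-0.05, -0.01, 0.0, 0.002)},
    "null": {"effect": (0.0, 0.0, 0.0, 0.0)},
    "income-groups": {
        "effects_by_income": {
            "high": (-0.01, -0.001, 0.0, 0.0015),
            "upper-middle": (-0.1, -0.02, 0.0, 0.0),
            "lower-middle": (-0.03, -0.005, 0.0, 0.001),
            "low": (-0.2, -0.04, 0.0, -0.002),
        }
    },
    "tax-split": {
        "effect_high_tax": (-0.1, -0.02, 0.0, 0.005),
        "effect_low_tax": (-0.04, -0.008, 0.0, -0.001),
    },
}

_INCOME_MIX = {"high": 0.30, "upper-middle": 0.29, "lower-middle": 0.28, "low": 0.13}


def _sample_country(
    rng: np.random.Generator,
    i: int,
    income: str,
    effect: tuple[float, float, float, float],
    high_tax: bool,
    trend_jitter_sd: float,
    noise_sd: float,
    ar1_rho: float,
) -> SimCountryParams:
    level, slope, quad, quit_drift = effect
    b1 = -0.02 + rng.normal(0.0, trend_jitter_sd)
    return SimCountryParams(
        country_id=f"C{i:03d}",
        ratification_year=int(
            rng.choice(list(RATIFICATION_YEAR_PMF), p=list(RATIFICATION_YEAR_PMF.values()))
        ),
        baseline_log_smokers=float(rng.normal(np.log(5e5), 1.0)),
        pre_trend=(b1, 0.0, 0.0),
        level_change=level,
        slope_change=slope,
        quad_change=quad,
        noise_sd=noise_sd,
        ar1_rho=ar1_rho,
        baseline_prevalence=float(rng.uniform(0.08, 0.25)),
        pop_growth=float(rng.uniform(0.0, 0.02)),
        baseline_quit_ratio=float(rng.uniform(0.2, 0.45)),
        quit_drift=quit_drift,
        income_group=income,
        tax_change_pp=float(rng.uniform(10, 25)) if high_tax else float(rng.uniform(-5, 9)),
        survey_years_count=int(rng.integers(4, 26)),
    )


def simulate_cohort(
    n_countries: int = 50,
    preset: str = "world",
    seed: int = 0,
    *,
    high_tax_fraction: float = 0.15,
    trend_jitter_sd: float = 0.0,
    noise_sd: float = 0.02,
    ar1_rho: float = 0.5,
    horizon: int = 10,
    window: WindowConfig = WindowConfig(),
    effect_override: tuple[float, float, float, float] | None = None,
) -> SimulatedCohort:
    """Simulate a full multi-country cohort under a named scenario preset.

    Returns the panel and meta tables (accepted unchanged by
    :mod:`smokeitsa.panel_io`) together with per-group ground truth.
    Presets: ``world`` (one shared effect profile), ``null`` (no effect),
    ``income-groups`` (income-specific profiles), ``tax-split``
    (high-tax-change countries get roughly double effects).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if n_countries < 1:
        raise ValueError("n_countries must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = PRESETS[preset]

    incomes = list(_INCOME_MIX)
    n_by_income = np.random.default_rng(seed + 1).multinomial(
        n_countries, list(_INCOME_MIX.values())
    )
    params: dict[str, SimCountryParams] = {}
    i = 0
    for income, count in zip(incomes, n_by_income):
        for _ in range(count):
            high_tax = bool(rng.random() < high_tax_fraction)
            if effect_override is not None:
                effect = effect_override
            elif "effect" in cfg:
                effect = cfg["effect"]
            elif "effects_by_income" in cfg:
                effect = cfg["effects_by_income"][income]
            else:
                effect = cfg["effect_high_tax"] if high_tax else cfg["effect_low_tax"]
            params[f"C{i:03d}"] = _sample_country(
                rng, i, income, effect, high_tax, trend_jitter_sd, noise_sd, ar1_rho
            )
            i += 1

    frames = [
        simulate_country(p, seed=np.random.default_rng(rng.integers(2**31)))
        for p in params.values()
    ]
    panel = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame(
        {
            "country": [p.country_id for p in params.values()],
            "ratification_year": [p.ratification_year for p in params.values()],
            "income_group": [p.income_group for p in params.values()],
            "tax_share_2008": [40.0] * len(params),
            "tax_change_pp": [p.tax_change_pp for p in params.values()],
            "survey_years_count": [p.survey_years_count for p in params.values()],
        }
    )

    members: dict[str, list[str]] = {"world": list(params)}
    for income in incomes:
        members[income] = [c for c, p in params.items() if p.income_group == income]
    members["high-tax-change"] = [
        c for c, p in params.items() if p.tax_change_pp is not None and p.tax_change_pp >= 10
    ]
    members["low-tax-change"] = [
        c for c, p in params.items() if p.tax_change_pp is not None and p.tax_change_pp < 10
    ]

    truth = SimTruth(horizon=horizon)
    for name, ids in members.items():
        if ids:
            truth.groups[name] = truth_from_noiseless_curves(
                [params[c] for c in ids], window, horizon
            )
    return SimulatedCohort(
        panel=panel, meta=meta, params=params, group_members=members, truth=truth
    )
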