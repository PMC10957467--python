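"""Event-time realignment and group aggregation of country smoking series.

Countries ratify at different calendar years, so before pooling, each
country's series is re-indexed to event time t = calendar_year -
ratification_year (t = 0 at ratification).  Group series are then sums of
member-country counts at each event time — prevalence and the quit ratio
are ratios of summed counts, not means of country ratios — and the three
log outcomes are taken on the aggregates:

* ``log_smokers``      log of current smokers aged 10-24
* ``log_prevalence``   log of (current smokers / population) aged 10-24
* ``log_quit_ratio``   log of (former / ever smokers) aged 45-59

Group membership must be identical at every event time; a member country
missing any window year is an error rather than a silently shrinking panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import AGE_YOUNG, AGE_OLD, GroupingScheme

__all__ = [
    "WindowConfig",
    "WindowCoverageError",
    "quit_ratio",
    "realign",
    "realign_panel",
    "aggregate_group",
    "OUTCOMES",
]

OUTCOMES = ("log_smokers", "log_prevalence", "log_quit_ratio")


@dataclass(frozen=True)
class WindowConfig:
    """Event-time analysis window around ratification.

    ``pre_window`` years before t = 0 and ``post_window`` after it
    (window length = pre + post + 1).  ``alt_start_rule`` treats countries
    ratifying before 2005 (when the treaty became binding) as ratifying in
    2005, a sensitivity variant.
    """

    pre_window: int = 10
    post_window: int = 10
    alt_start_rule: bool = False

    def __post_init__(self):
        if self.pre_window < 3:
            raise ValueError("pre_window must be >= 3")
        if self.post_window < 1:
            raise ValueError("post_window must be >= 1")

    @property
    def n_points(self) -> int:
        return self.pre_window + self.post_window + 1

    def event_times(self) -> np.ndarray:
        return np.arange(-self.pre_window, self.post_window + 1)

    def effective_year(self, ratification_year: int) -> int:
        if self.alt_start_rule and ratification_year < 2005:
            return 2005
        return int(ratification_year)


class WindowCoverageError(ValueError):
    """A country's data do not cover the full event-time window."""


def quit_ratio(former: float, ever: float) -> float:
    """Former-to-ever-smoker ratio, the cessation measure.

    Ever smokers = current + former; the ratio lies in (0, 1] and rises as
    a cohort quits.
    """
    if ever <= 0:
        raise ValueError(f"quit ratio undefined: ever smokers = {ever}")
    if former > ever:
        raise ValueError(f"former smokers ({former}) exceed ever smokers ({ever})")
    return former / ever


def realign(
    records: pd.DataFrame, ratification_year: int, window: WindowConfig = WindowConfig()
) -> pd.DataFrame:
    """Re-index one country's records to event time around its ratification.

    ``records`` is a validated long panel for a single country (columns as
    produced by :func:`smokeitsa.panel_io.read_panel`).  Returns the same
    rows restricted to the window, with an ``event_time`` column; raises
    :class:`WindowCoverageError` naming any missing years.  Realignment is
    a pure re-indexing — counts are untouched.
    """
    year0 = window.effective_year(ratification_year)
    out = records.copy()
    out["event_time"] = out["year"].astype(int) - year0
    out = out[(out["event_time"] >= -window.pre_window) & (out["event_time"] <= window.post_window)]
    for band in (AGE_YOUNG, AGE_OLD):
        got = set(out.loc[out["age_band"] == band, "event_time"])
        missing = sorted(set(window.event_times().tolist()) - got)
        if missing:
            country = records["country_id"].iloc[0] if len(records) else "?"
            years = [year0 + t for t in missing]
            raise WindowCoverageError(
                f"{country}: age band {band} missing years {years} "
                f"(window {year0 - window.pre_window}..{year0 + window.post_window})"
            )
    return out.sort_values(["age_band", "event_time"]).reset_index(drop=True)


def realign_panel(
    panel: pd.DataFrame,
    ratification_years: dict[str, int],
    window: WindowConfig = WindowConfig(),
) -> dict[str, pd.DataFrame]:
    """Realign every country in a validated panel; returns country -> series."""
    out = {}
    for country, records in panel.groupby("country_id", sort=True):
        if country not in ratification_years:
            continue
        out[country] = realign(records, ratification_years[country], window)
    return out


def aggregate_group(
    series_by_country: dict[str, pd.DataFrame],
    group: GroupingScheme,
    window: WindowConfig = WindowConfig(),
) -> pd.DataFrame:
    """Sum member-country counts at each event time and derive log outcomes.

    Returns a tidy frame with one row per event time: summed counts
    (``smokers_u25``, ``population_u25``, ``former_45_59``, ``ever_45_59``),
    and the three log outcomes computed from the sums.  Zero aggregates are
    an error (the logs must be finite).
    """
    missing = sorted(set(group.members) - set(series_by_country))
    if missing:
        raise ValueError(f"group '{group.name}': no realigned series for {missing}")
    if not group.members:
        raise ValueError(f"group '{group.name}' has no member countries")

    pieces = []
    for country in sorted(group.members):
        s = series_by_country[country]
        young = s[s["age_band"] == AGE_YOUNG].set_index("event_time")
        old = s[s["age_band"] == AGE_OLD].set_index("event_time")
        pieces.append(
            pd.DataFrame(
                {
                    "smokers_u25": young["current_smokers"],
                    "population_u25": young["population"],
                    "former_45_59": old["former_smokers"],
                    "ever_45_59": old["ever_smokers"],
                }
            )
        )
    total = sum(pieces[1:], pieces[0].copy()).sort_index()
    expected = window.event_times()
    if not np.array_equal(total.index.to_numpy(), expected):
        raise ValueError(
            f"group '{group.name}': aggregated event times {total.index.tolist()} "
            f"do not match the window {expected.tolist()}"
        )
    bad = total.columns[(total <= 0).any()].tolist()
    if bad:
        raise ValueError(f"group '{group.name}': zero or negative aggregate counts in {bad}")

    out = total.reset_index()
    out.insert(0, "group", group.name)
    out["log_smokers"] = np.log(out["smokers_u25"])
    prevalence = out["smokers_u25"] / out["population_u25"]
    if (prevalence > 1).any():
        raise ValueError(f"group '{group.name}': aggregate prevalence exceeds 1")
    out["log_prevalence"] = np.log(prevalence)
    out["log_quit_ratio"] = np.log(
        [quit_ratio(f, e) for f, e in zip(out["former_45_59"], out["ever_45_59"])]
    )
    return out
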