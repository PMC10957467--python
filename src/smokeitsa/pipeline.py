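"""End-to-end orchestration: group, realign, fit, select, summarize.

One call runs the full analysis for every group in a grouping scheme and
each of the three log outcomes: aggregate member counts in event time,
fit the five segmented specifications, keep the AIC-best, convert it to
trend-change and cumulative-effect summaries (delta-method CIs on the HAC
covariance, optionally country-bootstrap CIs as well), and project the
pre-trend to count averted smokers and additional quitters.  Outputs are
tidy frames plus a JSON-able summary; identical config and seed give
identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import effects as _effects
from .cohort import OUTCOMES, WindowConfig, aggregate_group, realign_panel
from .counterfactual import averted_from_fit
from .itsa import ITSAModelSelector
from .panel_io import GroupingScheme, build_grouping, read_meta, read_panel
from .uncertainty import BootstrapConfig, bootstrap_group, make_effect_statistic

__all__ = ["RunConfig", "RunResult", "run_pipeline", "run_pipeline_from_files"]

log = logging.getLogger("smokeitsa")


@dataclass
class RunConfig:
    """Settings for one pipeline run (defaults follow the main analysis)."""

    grouping: str = "world"
    window: WindowConfig = field(default_factory=WindowConfig)
    horizon: int = 10
    hac_lags: int | None = None  # None -> automatic floor(4*(n/100)^(2/9))
    aic_window: str = "full"  # or "pre": selection on pre-period residuals
    t0_is_post: bool = True
    averted_mode: str = "at_horizon"  # or "cumulative_person_years"
    exclude: tuple[str, ...] = ("CHN",)
    last_data_year: int = 2020
    quality_only: bool = False
    min_surveys: int = 10
    bootstrap: BootstrapConfig | None = field(default_factory=BootstrapConfig)
    seed: int = 0

    def __post_init__(self):
        if self.horizon > self.window.post_window:
            raise ValueError(
                f"horizon {self.horizon} exceeds post_window {self.window.post_window}"
            )


@dataclass
class RunResult:
    """All tables and the machine-readable summary from one run."""

    groups: list[GroupingScheme]
    group_series: dict[str, pd.DataFrame]
    effects_table: pd.DataFrame
    descriptive_table: pd.DataFrame
    counterfactual_table: pd.DataFrame
    summary: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.effects_table.to_csv(out / "effects.csv", index=False)
        self.descriptive_table.to_csv(out / "descriptive.csv", index=False)
        self.counterfactual_table.to_csv(out / "counterfactual.csv", index=False)
        pd.concat(self.group_series.values()).to_csv(out / "group_series.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)


_OUTCOME_TO_COUNT = {"log_smokers": "smokers_u25"}


def _descriptives(series: pd.DataFrame, window: WindowConfig) -> dict:
    def at(t):
        row = series.loc[series["event_time"] == t].iloc[0]
        return row

    d = {}
    for label, t in (
        ("pre", -window.pre_window),
        ("ratification", 0),
        ("post", window.post_window),
    ):
        row = at(t)
        d[f"prevalence_{label}"] = float(row["smokers_u25"] / row["population_u25"])
        d[f"smokers_{label}"] = float(row["smokers_u25"])
    row = at(0)
    d["former_ratification"] = float(row["former_45_59"])
    d["ever_ratification"] = float(row["ever_45_59"])
    d["quit_ratio_ratification"] = float(row["former_45_59"] / row["ever_45_59"])
    return d


def run_pipeline(
    panel: pd.DataFrame,
    metas: dict,
    config: RunConfig = RunConfig(),
    out_dir=None,
) -> RunResult:
    """Run the full analysis on a validated panel and country meta map."""
    groups = build_grouping(
        metas,
        config.grouping,
        exclude=config.exclude,
        last_data_year=config.last_data_year,
        post_window=config.window.post_window,
        quality_only=config.quality_only,
        min_surveys=config.min_surveys,
    )
    rat_years = {c: m.ratification_year for c, m in metas.items() if m.ratification_year}
    included = set().union(*(g.members for g in groups))
    series = realign_panel(
        panel[panel["country_id"].isin(included)], rat_years, config.window
    )
    for g in groups:
        for c in sorted(g.members):
            log.info("group %s includes %s", g.name, c)

    effects_rows, desc_rows, cf_rows = [], [], []
    summary: dict = {"config": {"grouping": config.grouping, "horizon": config.horizon}}
    group_series: dict[str, pd.DataFrame] = {}

    for gi, group in enumerate(groups):
        agg = aggregate_group(series, group, config.window)
        group_series[group.name] = agg
        gsum: dict = {"n_countries": len(group.members)}

        desc = _descriptives(agg, config.window)
        desc_rows.append({"group": group.name, "n_countries": len(group.members), **desc})
        gsum["descriptive"] = desc

        t = agg["event_time"].to_numpy(float)
        for outcome in OUTCOMES:
            sel = ITSAModelSelector(
                hac_lags=config.hac_lags,
                t0_is_post=config.t0_is_post,
                aic_window=config.aic_window,
            ).fit(t, agg[outcome].to_numpy(float))
            fit = sel.best_estimator_
            eff = _effects.summarize_effects(
                fit, group.name, outcome, horizon=config.horizon
            )
            row = {
                "group": group.name,
                "outcome": outcome,
                "model_id": sel.best_model_id_,
                "avg_pre_trend_pct": eff.avg_pre_trend.value,
                "avg_pre_trend_lo": eff.avg_pre_trend.ci_low,
                "avg_pre_trend_hi": eff.avg_pre_trend.ci_high,
                "trend_change_pct": eff.avg_trend_change.value,
                "trend_change_lo": eff.avg_trend_change.ci_low,
                "trend_change_hi": eff.avg_trend_change.ci_high,
                "cumulative_pct": eff.cumulative_effect.value,
                "cumulative_lo": eff.cumulative_effect.ci_low,
                "cumulative_hi": eff.cumulative_effect.ci_high,
                "ci_method": "delta_hac",
            }
            if config.bootstrap is not None and len(group.members) > 1:
                bcfg = BootstrapConfig(
                    n_replications=config.bootstrap.n_replications,
                    ci_level=config.bootstrap.ci_level,
                    # decorrelate streams across groups/outcomes
                    seed=config.bootstrap.seed + 1000 * gi + OUTCOMES.index(outcome),
                )
                boot = bootstrap_group(
                    series,
                    group,
                    make_effect_statistic(
                        outcome,
                        "cumulative_effect",
                        config.horizon,
                        config.hac_lags,
                        config.aic_window,
                        config.t0_is_post,
                    ),
                    bcfg,
                    config.window,
                )
                row["cumulative_boot_lo"] = boot.ci_low
                row["cumulative_boot_hi"] = boot.ci_high
            effects_rows.append(row)
            gsum[outcome] = {
                "model_id": sel.best_model_id_,
                "avg_pre_trend_pct": eff.avg_pre_trend.value,
                "trend_change_pct": eff.avg_trend_change.value,
                "cumulative_pct": eff.cumulative_effect.value,
                "cumulative_ci": [eff.cumulative_effect.ci_low, eff.cumulative_effect.ci_high],
            }

            # counterfactual counts for the log-count outcome and the quitters
            if outcome == "log_smokers":
                cf = averted_from_fit(
                    fit, group.name, config.horizon, mode=config.averted_mode
                )
                cf_rows.append(
                    {
                        "group": group.name,
                        "series": "smokers_u25",
                        "mode": cf.mode,
                        "projected": cf.projected_count,
                        "actual": cf.actual_count,
                        "averted": cf.averted,
                        "averted_pct": cf.averted_pct,
                    }
                )
                gsum["averted_smokers"] = cf.averted
                gsum["averted_pct"] = cf.averted_pct

        # additional quitters: same machinery on the log former-smoker count
        qsel = ITSAModelSelector(
            hac_lags=config.hac_lags, t0_is_post=config.t0_is_post, aic_window=config.aic_window
        ).fit(t, np.log(agg["former_45_59"].to_numpy(float)))
        qcf = averted_from_fit(qsel.best_estimator_, group.name, config.horizon)
        cf_rows.append(
            {
                "group": group.name,
                "series": "former_45_59",
                "mode": qcf.mode,
                "projected": qcf.projected_count,
                "actual": qcf.actual_count,
                "averted": qcf.averted,
                "averted_pct": qcf.averted_pct,
            }
        )
        gsum["additional_quitters"] = -qcf.averted  # more quitters than projected
        summary[group.name] = gsum

    result = RunResult(
        groups=groups,
        group_series=group_series,
        effects_table=pd.DataFrame(effects_rows),
        descriptive_table=pd.DataFrame(desc_rows),
        counterfactual_table=pd.DataFrame(cf_rows),
        summary=summary,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def run_pipeline_from_files(
    panel_path, meta_path, config: RunConfig = RunConfig(), out_dir=None
) -> RunResult:
    """File-based entry point: read and validate the CSVs, then run."""
    return run_pipeline(read_panel(panel_path), read_meta(meta_path), config, out_dir)
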