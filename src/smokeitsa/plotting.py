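"""Simple trajectory plots of group series and counterfactual projections."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counterfactual import CounterfactualResult

__all__ = ["plot_group_outcome", "plot_counterfactual"]


def plot_group_outcome(group_df: pd.DataFrame, outcome: str = "log_smokers", ax=None):
    """Plot one group's outcome against event time, marking the event year."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(group_df["event_time"], group_df[outcome], marker="o", ms=3)
    ax.axvline(0, color="grey", ls="--", lw=1)
    ax.set_xlabel("years since ratification")
    ax.set_ylabel(outcome)
    ax.set_title(str(group_df["group"].iloc[0]))
    return ax


def plot_counterfactual(result: CounterfactualResult, ax=None):
    """Projected pre-trend vs actual counts over the post period."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = np.arange(result.horizon + 1)
    ax.plot(t, result.projected_path, ls="--", label="projected (pre-trend)")
    ax.plot(t, result.actual_path, label="actual")
    ax.set_xlabel("years since ratification")
    ax.set_ylabel("persons")
    ax.legend()
    ax.set_title(f"{result.group}: {result.averted:,.0f} averted ({result.averted_pct:.1f}%)")
    return ax
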