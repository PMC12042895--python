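"""Figure panels for the foraging and intertidal trend results.

Line-plus-credible-ribbon panels for effort and energy trajectories, the
four-panel scenario comparison, spline trend panels with standard-error
ribbons, and pre/post frequency histograms. All functions return the
matplotlib figure so callers can save or embed it.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .intertidal import PrePostSummary, SplineTrend
from .scenarios import ScenarioResult

__all__ = [
    "plot_effort",
    "plot_scenarios",
    "plot_trend",
    "plot_prepost_histograms",
]

_COLORS = {"mussel": "#d95f02", "urchin": "#7570b3"}


def plot_effort(
    baseline: ScenarioResult,
    prey: tuple[str, ...] = ("mussel", "urchin"),
    ssw_year: int = 2013,
):
    """Effort-allocation trajectories with 95% credible ribbons."""
    fig, ax = plt.subplots(figsize=(7, 4))
    eff = baseline.effort
    for p in prey:
        sub = eff[eff["prey_id"] == p]
        color = _COLORS.get(p)
        ax.plot(sub["year"], sub["mean"], label=p, color=color)
        ax.fill_between(sub["year"], sub["lo95"], sub["hi95"],
                        alpha=0.25, color=color)
    ax.axvline(ssw_year, ls=":", color="k", lw=1)
    ax.set_xlabel("year")
    ax.set_ylabel("proportion of foraging effort")
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_scenarios(results: dict[str, ScenarioResult], ssw_year: int = 2013):
    """Four-panel comparison of energy intake under prey-dynamics scenarios."""
    names = [n for n in results if n != "baseline"]
    base = results["baseline"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True, sharey=True)
    panels = [("baseline", None)] + [(n, results[n]) for n in names[:3]]
    for ax, (name, res) in zip(axes.ravel(), panels):
        ax.fill_between(base.years, base.energy_lo, base.energy_hi,
                        color="0.8", label="baseline band")
        ax.plot(base.years, base.energy_mean, color="0.4")
        if res is not None:
            ax.plot(res.years, res.energy_mean, color="#1b9e77")
            ax.fill_between(res.years, res.energy_lo, res.energy_hi,
                            alpha=0.3, color="#1b9e77")
        ax.axvline(ssw_year, ls=":", color="k", lw=1)
        ax.set_title(name)
    for ax in axes[-1]:
        ax.set_xlabel("year")
    for ax in axes[:, 0]:
        ax.set_ylabel("energy intake (kcal/min)")
    fig.tight_layout()
    return fig


def plot_trend(
    years,
    values,
    trend: SplineTrend | None = None,
    extrapolation: pd.DataFrame | None = None,
    ssw_year: int = 2013,
    ylabel: str = "",
):
    """Yearly points with a smoothing-spline trend and SE ribbon."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(years, values, "o", color="k", ms=4)
    if trend is not None:
        ax.plot(trend.years, trend.fitted, color="#1b9e77")
        if trend.stderr is not None:
            ax.fill_between(trend.years, trend.fitted - trend.stderr,
                            trend.fitted + trend.stderr,
                            alpha=0.3, color="#1b9e77")
    if extrapolation is not None:
        ax.plot(extrapolation["year"], extrapolation["value"], "--o",
                color="0.6", ms=4)
    ax.axvline(ssw_year, ls=":", color="k", lw=1)
    ax.set_xlabel("year")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return fig


def plot_prepost_histograms(summary: PrePostSummary):
    """Pre vs post frequency distributions of distance, size and cover."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    labels = {"distance": "distance from baseline (m)",
              "size": "mussel size (mm)", "cover": "percent cover"}
    for ax, (name, table) in zip(axes, summary.tables.items()):
        for period, color in (("pre", "#4575b4"), ("post", "#d73027")):
            sub = table[table["period"] == period]
            ax.bar(sub["bin_left"], sub["count"],
                   width=sub["bin_right"] - sub["bin_left"],
                   align="edge", alpha=0.5, color=color, label=period)
        ax.set_xlabel(labels.get(name, name))
        ax.set_ylabel("frequency")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    return fig
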