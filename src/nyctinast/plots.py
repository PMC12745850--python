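"""Display figures: motion traces, cell-mean profiles, learning curves.

All statistics are computed elsewhere; smoothing here is display-only.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .motion import FrameSeries, gaussian_smooth
from .schedule import CONDITIONS, INTERVALS, LightingSchedule
from .stats import CellTable, LearningCurveResults

__all__ = [
    "plot_motion_trace",
    "plot_cell_means",
    "plot_learning_curve",
    "plot_difference_by_day_length",
]


def plot_motion_trace(
    series: FrameSeries,
    schedule: LightingSchedule | None = None,
    smooth_window: int = 50,
    path=None,
):
    """Raw and Gaussian-smoothed motion trace; light-on spans shaded."""
    fig, ax = plt.subplots(figsize=(10, 3.2))
    t_h = series.timestamps_s / 3600.0
    raw = np.where(series.valid, series.motion, np.nan)
    ax.plot(t_h, raw, lw=0.3, color="0.6", label="per-frame motion")
    filled = np.nan_to_num(raw, nan=np.nanmean(raw))
    ax.plot(t_h, gaussian_smooth(filled, smooth_window), lw=1.2, color="tab:green",
            label=f"smoothed (window {smooth_window})")
    if schedule is not None:
        for seg in schedule.segments:
            if seg.light_state == "on":
                ax.axvspan(seg.start_s / 3600, seg.end_s / 3600, color="gold", alpha=0.15)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("motion (mean |ΔG|)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_cell_means(table: CellTable, path=None):
    """Across-cycle mean ± SEM per (condition, time-of-day) cell."""
    summ = table.condition_interval_summary()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    width = 0.25
    xs = np.arange(len(INTERVALS))
    for k, cond in enumerate(CONDITIONS):
        sub = summ[summ["condition"] == cond].set_index("interval").reindex(list(INTERVALS))
        ax.bar(xs + (k - 1) * width, sub["Mean"], width, yerr=sub["SEM"],
               label=cond, capsize=3)
    ax.set_xticks(xs, INTERVALS)
    ax.set_ylabel("mean motion")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_learning_curve(
    differences: pd.Series, fit: LearningCurveResults | None = None, path=None
):
    """Per-cycle motion difference with the fitted log curve."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.axhline(0, color="0.7", lw=0.8)
    ax.plot(differences.index, differences.values, "o", color="tab:green", ms=5)
    if fit is not None:
        grid = np.linspace(min(differences.index), max(differences.index), 200)
        ax.plot(grid, fit.predict(grid), "-", color="0.3",
                label=f"{fit.slope:.2f}·log(c) {fit.intercept:+.2f} (r²={fit.rsquared:.2f})")
        ax.legend(fontsize=8)
    ax.set_xlabel("cycle number")
    ax.set_ylabel("motion difference\n(L1+L2)/2 − Dark, pre-light")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_difference_by_day_length(
    differences: pd.Series, day_lengths: pd.Series, band=(12.0, 24.0), path=None
):
    """Motion difference as a function of the cycle's day length."""
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    ax.axhline(0, color="0.7", lw=0.8)
    ax.axvspan(band[0], band[1], color="tab:green", alpha=0.1, label="anticipation band")
    n = day_lengths.reindex(differences.index)
    ax.plot(n, differences.values, "o", color="tab:green", ms=5)
    ax.set_xlabel("day length N (h)")
    ax.set_ylabel("motion difference")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
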