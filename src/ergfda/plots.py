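"""Figure helpers: pointwise boxplots, group summary bands, comparisons.

Figures are views — every number drawn here is also written to CSV by the
pipeline.  Each helper returns a matplotlib ``Figure``; :func:`save_figure`
writes SVG and PNG side by side.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib.pyplot as plt
import numpy as np

from .compare import ComparisonResult
from .summaries import BoxplotSeries, SummaryCurve

__all__ = [
    "save_figure",
    "pointwise_boxplot_figure",
    "group_summary_figure",
    "comparison_figure",
]

_COLORS = ("tab:blue", "tab:orange", "tab:green", "tab:red")


def save_figure(fig, stem) -> list[Path]:
    """Write ``<stem>.svg`` and ``<stem>.png``; return the paths."""
    stem = Path(stem)
    paths = []
    for ext in ("svg", "png"):
        p = stem.with_suffix(f".{ext}")
        fig.savefig(p, bbox_inches="tight", dpi=150)
        paths.append(p)
    plt.close(fig)
    return paths


def _axis_label(axis: str) -> tuple[str, str]:
    if axis == "registered":
        return "registered time", "registered amplitude"
    return "time (ms)", "amplitude (µV)"


def pointwise_boxplot_figure(
    series_by_group: Mapping[str, BoxplotSeries], axis: str = "raw"
):
    """Pointwise Tukey boxplots per group: IQR band, median line,
    whisker envelope, outlier dots."""
    if not series_by_group:
        raise ValueError("no boxplot series to plot")
    xlab, ylab = _axis_label(axis)
    fig, axes = plt.subplots(
        1, len(series_by_group), figsize=(5.5 * len(series_by_group), 4), sharey=True
    )
    axes = np.atleast_1d(axes)
    for ax, (label, bx) in zip(axes, series_by_group.items()):
        ax.fill_between(bx.grid, bx.whisker_low, bx.whisker_high, alpha=0.2,
                        color="tab:gray", label="whisker range")
        ax.fill_between(bx.grid, bx.q1, bx.q3, alpha=0.45, color="tab:blue",
                        label="IQR")
        ax.plot(bx.grid, bx.median, color="black", lw=1.2, label="median")
        xs, ys = [], []
        for x, pts in zip(bx.grid, bx.outliers):
            for _, v in pts:
                xs.append(x)
                ys.append(v)
        if xs:
            ax.plot(xs, ys, ".", color="black", ms=3, label="outliers")
        ax.set_title(label)
        ax.set_xlabel(xlab)
    axes[0].set_ylabel(ylab)
    axes[0].legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    return fig


def group_summary_figure(
    trajectories: Mapping[str, tuple[np.ndarray, np.ndarray]],
    location: Mapping[str, SummaryCurve],
    scale: Mapping[str, SummaryCurve],
    axis: str = "raw",
):
    """Three panels: individual trajectories, location ± CI, scale ± CI.

    ``trajectories`` maps group label to (grid, matrix-of-rows).
    """
    if not location:
        raise ValueError("no summary curves to plot")
    xlab, ylab = _axis_label(axis)
    fig, (ax_raw, ax_loc, ax_sc) = plt.subplots(1, 3, figsize=(15, 4))
    for color, (label, (grid, mat)) in zip(_COLORS, trajectories.items()):
        ax_raw.plot(grid, np.asarray(mat).T, color=color, alpha=0.25, lw=0.6)
        ax_raw.plot([], [], color=color, label=label)
    ax_raw.set_title("individual trajectories")
    for ax, curves, what in ((ax_loc, location, "location"), (ax_sc, scale, "scale")):
        for color, (label, c) in zip(_COLORS, curves.items()):
            ax.fill_between(c.grid, c.ci_low, c.ci_high, alpha=0.3, color=color)
            ax.plot(c.grid, c.estimate, color=color, label=label)
        first = next(iter(curves.values()))
        ax.set_title(f"{first.estimator} ({what}) ± 95% pointwise CI")
    for ax in (ax_raw, ax_loc, ax_sc):
        ax.set_xlabel(xlab)
        ax.legend(fontsize=8)
        if axis == "registered":
            ax.set_xlim(0.0, 1.0)
    ax_raw.set_ylabel(ylab)
    fig.tight_layout()
    return fig


def comparison_figure(result: ComparisonResult, axis: str = "raw"):
    """Two bands plus tick marks over the significant intervals."""
    if result.grid.size == 0:
        raise ValueError("empty comparison")
    xlab, ylab = _axis_label(axis)
    fig, ax = plt.subplots(figsize=(7, 4.2))
    for color, (label, curve) in zip(
        _COLORS, zip(result.labels, (result.curve_a, result.curve_b))
    ):
        ax.fill_between(curve.grid, curve.ci_low, curve.ci_high, alpha=0.3, color=color)
        ax.plot(curve.grid, curve.estimate, color=color, label=label)
    ylo = min(result.curve_a.ci_low.min(), result.curve_b.ci_low.min())
    for start, end in result.significant_intervals:
        ax.axvspan(start, end, color="tab:red", alpha=0.12)
        ax.plot([start, end], [ylo, ylo], color="tab:red", lw=3,
                solid_capstyle="butt")
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    if axis == "registered":
        ax.set_xlim(0.0, 1.0)
    ax.legend(fontsize=8)
    ax.set_title(
        f"{result.curve_a.estimator} comparison — significant where bands do not overlap"
    )
    fig.tight_layout()
    return fig
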