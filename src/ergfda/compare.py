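"""Pointwise group comparison by confidence-interval overlap.

Two groups' summary curves are compared grid point by grid point: where
the two pointwise 95% bands share no point, the difference is declared
significant at the 5% level; maximal runs of such points are reported as
significant intervals.  Bands that merely touch at an endpoint count as
overlapping (not significant).  The rule is conservative — non-overlap of
two 95% intervals corresponds to a test below the nominal 5% level — and
is applied independently at each grid point with no multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .summaries import BootstrapSpec, SummaryCurve, location_curve, scale_curve

__all__ = [
    "ComparisonResult",
    "SeparationPoint",
    "overlap_scan",
    "best_separation_point",
    "compare_groups",
]


@dataclass(frozen=True)
class SeparationPoint:
    """The grid point where the CI boundaries are furthest apart.

    ``gap`` is the signed distance between the nearer CI boundaries:
    positive where the bands are disjoint, <= 0 where they overlap.
    ``significant`` is False when no grid point is significant, in which
    case the point of least overlap is reported instead.
    """

    grid_value: float
    gap: float
    significant: bool


@dataclass(frozen=True)
class ComparisonResult:
    """Two summary curves plus the pointwise non-overlap scan."""

    grid: np.ndarray
    curve_a: SummaryCurve
    curve_b: SummaryCurve
    non_overlap: np.ndarray  # bool per grid point
    gap: np.ndarray  # signed CI-boundary gap per grid point
    significant_intervals: tuple  # ((start, end) grid coordinates, ...)
    labels: tuple[str, str] = ("group_a", "group_b")

    @property
    def max_separation(self) -> SeparationPoint:
        return best_separation_point(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.grid,
                f"estimate_{self.labels[0]}": self.curve_a.estimate,
                f"ci_low_{self.labels[0]}": self.curve_a.ci_low,
                f"ci_high_{self.labels[0]}": self.curve_a.ci_high,
                f"estimate_{self.labels[1]}": self.curve_b.estimate,
                f"ci_low_{self.labels[1]}": self.curve_b.ci_low,
                f"ci_high_{self.labels[1]}": self.curve_b.ci_high,
                "gap": self.gap,
                "non_overlap": self.non_overlap,
            }
        )

    def intervals_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.significant_intervals, columns=["start", "end"])


def _maximal_runs(mask: np.ndarray, grid: np.ndarray) -> tuple:
    """Collapse True runs of ``mask`` to (grid[start], grid[end]) pairs."""
    intervals = []
    j = 0
    n = mask.size
    while j < n:
        if mask[j]:
            start = j
            while j + 1 < n and mask[j + 1]:
                j += 1
            intervals.append((float(grid[start]), float(grid[j])))
        j += 1
    return tuple(intervals)


def overlap_scan(
    curve_a: SummaryCurve,
    curve_b: SummaryCurve,
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> ComparisonResult:
    """Scan two same-grid summary curves for CI non-overlap.

    Point j is significant iff one band lies strictly above the other
    (shared endpoints overlap); maximal runs become significant intervals.
    """
    if curve_a.estimator != curve_b.estimator:
        raise ValueError(
            f"estimator mismatch: {curve_a.estimator!r} vs {curve_b.estimator!r}"
        )
    if curve_a.grid.shape != curve_b.grid.shape or not np.array_equal(
        curve_a.grid, curve_b.grid
    ):
        raise ValueError("summary curves are not on the same grid")
    gap = np.maximum(
        curve_a.ci_low - curve_b.ci_high, curve_b.ci_low - curve_a.ci_high
    )
    non_overlap = gap > 0.0
    return ComparisonResult(
        grid=curve_a.grid,
        curve_a=curve_a,
        curve_b=curve_b,
        non_overlap=non_overlap,
        gap=gap,
        significant_intervals=_maximal_runs(non_overlap, curve_a.grid),
        labels=labels,
    )


def best_separation_point(result: ComparisonResult) -> SeparationPoint:
    """Locate the grid point with the widest CI gap (ties -> earliest).

    Among significant points if any exist; otherwise the point of least
    band overlap is returned with its (non-positive) gap and the
    ``significant`` flag cleared.
    """
    if result.grid.size == 0:
        raise ValueError("empty grid")
    if result.non_overlap.any():
        idx = np.flatnonzero(result.non_overlap)
        j = idx[int(np.argmax(result.gap[idx]))]  # argmax -> first maximum
        return SeparationPoint(float(result.grid[j]), float(result.gap[j]), True)
    j = int(np.argmax(result.gap))
    return SeparationPoint(float(result.grid[j]), float(result.gap[j]), False)


def _child_boot(boot: BootstrapSpec, index: int) -> BootstrapSpec:
    """Derive an independent, deterministic child seed per group."""
    child = np.random.SeedSequence(boot.seed).spawn(2)[index]
    seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
    return BootstrapSpec(boot.n_boot, seed, boot.cluster_ids)


def compare_groups(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    grid=None,
    estimator: str = "mean",
    alpha: float = 0.05,
    boot: BootstrapSpec | None = None,
    axis: str = "raw",
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> ComparisonResult:
    """Build both groups' summary curves and run the overlap scan.

    End-to-end deterministic: bootstrap-based estimators get per-group
    child seeds derived from ``boot.seed``.
    """
    for name, m in zip(labels, (matrix_a, matrix_b)):
        m = np.asarray(m)
        if m.ndim != 2 or m.shape[0] < 2:
            raise ValueError(f"group {name!r} needs at least 2 curves")
    boot = boot or BootstrapSpec()
    curves = []
    for i, m in enumerate((matrix_a, matrix_b)):
        b = _child_boot(boot, i)
        if estimator in ("mean", "median"):
            curves.append(location_curve(m, grid, estimator, alpha, b, axis))
        elif estimator in ("sd", "mad"):
            curves.append(scale_curve(m, grid, estimator, alpha, b, axis))
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    return overlap_scan(curves[0], curves[1], labels)
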