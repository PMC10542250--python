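"""Time-pointwise location/scale summary curves with 95% confidence bands.

Given a matrix of amplitudes (one row per waveform, one column per grid
point), this module computes, independently at every grid point:

* location — the arithmetic mean (t-based CI) or the sample median
  (percentile-bootstrap CI);
* scale — the sample standard deviation (n-1 denominator) or the median
  absolute deviation (percentile-bootstrap CIs for both);
* Tukey boxplot statistics (quartiles, 1.5·IQR whiskers, outliers).

The bands are *pointwise*: each interval is a marginal 95% interval with
no simultaneous (family-wise) guarantee.  Bootstrap resampling is over
rows (waveforms) and fully seeded; an optional cluster bootstrap resamples
participants instead of waveforms, for sensitivity to within-participant
(two-eye) correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BootstrapSpec",
    "SummaryCurve",
    "BoxplotSeries",
    "SummaryBundle",
    "location_curve",
    "scale_curve",
    "boxplot_series",
    "summary_bundle",
]

MAD_CONSISTENCY = 1.4826  # Gaussian consistency factor, optional

_MAD_KINDS = ("median_about_median", "mean_about_mean", "mean_about_median")


@dataclass(frozen=True)
class BootstrapSpec:
    """Seeded percentile bootstrap: ``n_boot`` row resamples.

    If ``cluster_ids`` is given (one label per row), whole clusters —
    typically participants contributing both eyes — are resampled with
    replacement instead of individual rows.
    """

    n_boot: int = 1000
    seed: int = 0
    cluster_ids: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError(f"bootstrap needs at least 1 replicate, got {self.n_boot}")
        if self.cluster_ids is not None:
            object.__setattr__(self, "cluster_ids", tuple(self.cluster_ids))


@dataclass(frozen=True)
class SummaryCurve:
    """One pointwise estimate with its pointwise confidence band."""

    grid: np.ndarray
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: np.ndarray
    estimator: str  # mean | median | sd | mad
    alpha: float = 0.05
    axis: str = "raw"  # raw | registered

    def __post_init__(self) -> None:
        for name in ("grid", "estimate", "ci_low", "ci_high"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "n", np.asarray(self.n, dtype=int))
        if not (
            self.grid.shape
            == self.estimate.shape
            == self.ci_low.shape
            == self.ci_high.shape
            == self.n.shape
        ):
            raise ValueError("summary curve arrays must share one shape")
        if np.any(self.ci_low > self.estimate) or np.any(self.ci_high < self.estimate):
            raise ValueError("confidence band must contain the estimate at every point")
        if self.estimator in ("sd", "mad") and np.any(self.estimate < 0):
            raise ValueError("scale estimates must be non-negative")


@dataclass(frozen=True)
class BoxplotSeries:
    """Pointwise Tukey boxplot statistics across waveforms."""

    grid: np.ndarray
    median: np.ndarray
    q1: np.ndarray
    q3: np.ndarray
    whisker_low: np.ndarray
    whisker_high: np.ndarray
    outliers: tuple  # per grid point: tuple of (waveform_id, amplitude)


def _check_matrix(matrix: np.ndarray, min_rows: int = 2) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("amplitude matrix must be 2-D (waveforms x grid)")
    if m.shape[0] < min_rows:
        raise ValueError(
            f"pointwise statistics need at least {min_rows} waveforms, got {m.shape[0]}"
        )
    if not np.all(np.isfinite(m)):
        raise ValueError("amplitude matrix contains missing/non-finite cells")
    return m


def _default_grid(matrix: np.ndarray, grid) -> np.ndarray:
    if grid is None:
        return np.arange(matrix.shape[1], dtype=float)
    g = np.asarray(grid, dtype=float)
    if g.shape != (matrix.shape[1],):
        raise ValueError("grid length must match the matrix column count")
    return g


def _bootstrap_band(
    matrix: np.ndarray,
    stat: Callable[[np.ndarray], np.ndarray],
    estimate: np.ndarray,
    alpha: float,
    boot: BootstrapSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap over rows (or clusters of rows).

    The returned band is widened, where necessary, to contain the full-
    sample estimate, preserving the band invariant at extreme n.
    """
    rng = np.random.default_rng(boot.seed)
    n = matrix.shape[0]
    reps = np.empty((boot.n_boot, matrix.shape[1]))
    if boot.cluster_ids is None:
        for b in range(boot.n_boot):
            idx = rng.integers(0, n, size=n)
            reps[b] = stat(matrix[idx])
    else:
        if len(boot.cluster_ids) != n:
            raise ValueError("cluster_ids must give one label per matrix row")
        labels = np.asarray(boot.cluster_ids)
        clusters = [np.flatnonzero(labels == c) for c in dict.fromkeys(boot.cluster_ids)]
        k = len(clusters)
        for b in range(boot.n_boot):
            pick = rng.integers(0, k, size=k)
            idx = np.concatenate([clusters[j] for j in pick])
            reps[b] = stat(matrix[idx])
    lo = np.quantile(reps, alpha / 2, axis=0)
    hi = np.quantile(reps, 1 - alpha / 2, axis=0)
    return np.minimum(lo, estimate), np.maximum(hi, estimate)


def _mad(matrix: np.ndarray, kind: str, scale: float) -> np.ndarray:
    if kind == "median_about_median":
        center = np.median(matrix, axis=0)
        out = np.median(np.abs(matrix - center), axis=0)
    elif kind == "mean_about_mean":
        center = matrix.mean(axis=0)
        out = np.abs(matrix - center).mean(axis=0)
    elif kind == "mean_about_median":
        center = np.median(matrix, axis=0)
        out = np.abs(matrix - center).mean(axis=0)
    else:
        raise ValueError(f"mad_kind must be one of {_MAD_KINDS}, got {kind!r}")
    return scale * out


def location_curve(
    matrix: np.ndarray,
    grid=None,
    estimator: str = "mean",
    alpha: float = 0.05,
    boot: BootstrapSpec | None = None,
    axis: str = "raw",
) -> SummaryCurve:
    """Pointwise location curve with a pointwise (1-alpha) band.

    ``mean`` uses the classical t-interval  mean ± t_{1-α/2, n-1}·s/√n;
    ``median`` uses a seeded percentile bootstrap over rows.
    """
    m = _check_matrix(matrix)
    g = _default_grid(m, grid)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n = m.shape[0]
    if estimator == "mean":
        est = m.mean(axis=0)
        se = m.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
        lo, hi = est - tcrit * se, est + tcrit * se
    elif estimator == "median":
        est = np.median(m, axis=0)
        boot = boot or BootstrapSpec()
        lo, hi = _bootstrap_band(m, lambda a: np.median(a, axis=0), est, alpha, boot)
    else:
        raise ValueError(f"location estimator must be 'mean' or 'median', got {estimator!r}")
    return SummaryCurve(g, est, lo, hi, np.full(g.shape, n), estimator, alpha, axis)


def scale_curve(
    matrix: np.ndarray,
    grid=None,
    estimator: str = "sd",
    alpha: float = 0.05,
    boot: BootstrapSpec | None = None,
    axis: str = "raw",
    mad_kind: str = "median_about_median",
    mad_scale: float = 1.0,
) -> SummaryCurve:
    """Pointwise scale curve with a seeded percentile-bootstrap band.

    ``sd`` is the sample standard deviation (n-1 denominator).  ``mad``
    defaults to the median absolute deviation about the median, unscaled;
    ``mad_kind`` selects mean-based variants and ``mad_scale`` can apply
    the Gaussian consistency factor :data:`MAD_CONSISTENCY`.
    """
    m = _check_matrix(matrix)
    g = _default_grid(m, grid)
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    n = m.shape[0]
    boot = boot or BootstrapSpec()
    if estimator == "sd":
        stat = lambda a: a.std(axis=0, ddof=1)
    elif estimator == "mad":
        stat = lambda a: _mad(a, mad_kind, mad_scale)
    else:
        raise ValueError(f"scale estimator must be 'sd' or 'mad', got {estimator!r}")
    est = stat(m)
    lo, hi = _bootstrap_band(m, stat, est, alpha, boot)
    lo = np.maximum(lo, 0.0)
    return SummaryCurve(g, est, lo, hi, np.full(g.shape, n), estimator, alpha, axis)


def _quartiles(col: np.ndarray, method: str) -> tuple[float, float, float]:
    if method == "linear":
        q1, med, q3 = np.percentile(col, [25, 50, 75])
    elif method == "hinges":
        s = np.sort(col)
        n = s.size
        med = float(np.median(s))
        half = (n + 1) // 2
        q1 = float(np.median(s[:half]))
        q3 = float(np.median(s[n - half:]))
    else:
        raise ValueError(f"quartile method must be 'linear' or 'hinges', got {method!r}")
    return float(q1), float(med), float(q3)


def boxplot_series(
    matrix: np.ndarray,
    grid=None,
    ids: Sequence[str] | None = None,
    quartile_method: str = "linear",
) -> BoxplotSeries:
    """Pointwise Tukey boxplots: quartiles by linear interpolation of order
    statistics (or classical hinges), whiskers at the most extreme data
    within 1.5·IQR of the quartiles, points beyond flagged as outliers."""
    m = _check_matrix(matrix)
    g = _default_grid(m, grid)
    row_ids = list(ids) if ids is not None else [f"row{i}" for i in range(m.shape[0])]
    if len(row_ids) != m.shape[0]:
        raise ValueError("ids must give one label per matrix row")
    med = np.empty(g.size)
    q1 = np.empty(g.size)
    q3 = np.empty(g.size)
    wlo = np.empty(g.size)
    whi = np.empty(g.size)
    outliers = []
    for j in range(g.size):
        col = m[:, j]
        lo_q, md, hi_q = _quartiles(col, quartile_method)
        iqr = hi_q - lo_q
        lo_fence, hi_fence = lo_q - 1.5 * iqr, hi_q + 1.5 * iqr
        inside = (col >= lo_fence) & (col <= hi_fence)
        med[j], q1[j], q3[j] = md, lo_q, hi_q
        wlo[j] = col[inside].min()
        whi[j] = col[inside].max()
        outliers.append(
            tuple(
                (row_ids[i], float(col[i]))
                for i in np.flatnonzero(~inside)
            )
        )
    return BoxplotSeries(g, med, q1, q3, wlo, whi, tuple(outliers))


@dataclass(frozen=True)
class SummaryBundle:
    """All five pointwise products of one amplitude matrix."""

    mean: SummaryCurve
    median: SummaryCurve
    sd: SummaryCurve
    mad: SummaryCurve
    boxplots: BoxplotSeries

    def __getitem__(self, key: str) -> SummaryCurve:
        if key not in ("mean", "median", "sd", "mad"):
            raise KeyError(key)
        return getattr(self, key)


def summary_bundle(
    matrix: np.ndarray,
    grid=None,
    ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    boot: BootstrapSpec | None = None,
    axis: str = "raw",
    mad_kind: str = "median_about_median",
    mad_scale: float = 1.0,
) -> SummaryBundle:
    """Mean, median, SD and MAD curves plus boxplot statistics, all from
    the same matrix on the same grid."""
    boot = boot or BootstrapSpec()
    return SummaryBundle(
        mean=location_curve(matrix, grid, "mean", alpha, boot, axis),
        median=location_curve(matrix, grid, "median", alpha, boot, axis),
        sd=scale_curve(matrix, grid, "sd", alpha, boot, axis),
        mad=scale_curve(matrix, grid, "mad", alpha, boot, axis, mad_kind, mad_scale),
        boxplots=boxplot_series(matrix, grid, ids),
    )
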