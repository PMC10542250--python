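"""Piecewise-linear (polygonal-basis) functional representation of traces.

Each discrete trace is treated as a functional observation: the polygonal
curve through its samples.  Evaluation is exact linear interpolation
between bracketing knots; extrapolation is always refused, so callers must
window query grids to the curve's domain.  The same type serves raw
(ms/µV) and registered (unit-square) axes — axis semantics are metadata,
not behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PolygonalCurve"]


@dataclass(frozen=True)
class PolygonalCurve:
    """A piecewise-linear curve through strictly increasing knots."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
            raise ValueError("knot x and y must be 1-D arrays of equal length")
        if x.size < 2:
            raise ValueError("a polygonal curve needs at least 2 knots")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("knots must be finite")
        if not np.all(np.diff(x) > 0):
            raise ValueError("knot x values must be strictly increasing")

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def evaluate(self, x: float | np.ndarray) -> float | np.ndarray:
        """Linear interpolation at ``x``; exact knot values at knots.

        Raises for any query outside [first knot, last knot] — there is no
        extrapolation.
        """
        scalar = np.isscalar(x) or np.ndim(x) == 0
        xq = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.domain
        outside = (xq < lo) | (xq > hi)
        if outside.any():
            bad = float(xq[outside][0])
            raise ValueError(
                f"query point {bad} outside curve domain [{lo}, {hi}]"
            )
        out = np.interp(xq, self.x, self.y)
        return float(out[0]) if scalar else out

    __call__ = evaluate

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate on a strictly increasing grid within the domain.

        Resampling onto the curve's own knots is the identity.
        """
        g = np.asarray(grid, dtype=float)
        if g.ndim != 1 or g.size < 1:
            raise ValueError("grid must be a non-empty 1-D array")
        if g.size > 1 and not np.all(np.diff(g) > 0):
            raise ValueError("grid must be strictly increasing")
        return self.evaluate(g)
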