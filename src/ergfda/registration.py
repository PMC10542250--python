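"""Two-landmark affine registration of AL-b segments onto the unit square.

Each AL-b segment is mapped so that the a-wave minimum becomes (0, 0) and
the b-wave maximum becomes (1, 1):

    u = (t - t_a) / (t_b - t_a),    w = (v - v_a) / (v_b - v_a).

This removes inter-individual phase (latency) and amplitude variability
while preserving the shape of the ascending limb, and is invariant under
any positive affine transform of either raw axis.  No time-warping beyond
the two landmarks is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import PolygonalCurve
from .landmarks import LandmarkPair, Segment

__all__ = [
    "DEFAULT_GRID_POINTS",
    "RegisteredCurve",
    "RegisteredEnsemble",
    "register_segment",
    "resample_registered",
    "register_cohort",
]

logger = logging.getLogger(__name__)

#: Default number of points of the shared registered grid (step 0.01, so
#: registered time 0.6 is an exact grid column).
DEFAULT_GRID_POINTS = 101


@dataclass(frozen=True)
class RegisteredCurve:
    """An AL-b segment on registered axes u, w ∈ [0, 1]."""

    waveform_id: str
    u: np.ndarray
    w: np.ndarray
    source_landmarks: LandmarkPair
    group: str = ""

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "w", w)
        if u.shape != w.shape or u.ndim != 1 or u.size < 2:
            raise ValueError("registered u and w must be equal-length 1-D arrays (>= 2)")
        if u[0] != 0.0 or u[-1] != 1.0 or w[0] != 0.0 or w[-1] != 1.0:
            raise ValueError("registered curve must start at (0,0) and end at (1,1)")
        if not np.all(np.diff(u) > 0):
            raise ValueError("registered times must be strictly increasing")
        if w.min() < 0.0 or w.max() > 1.0:
            raise ValueError("registered amplitudes must lie in [0, 1]")

    def curve(self) -> PolygonalCurve:
        return PolygonalCurve(self.u, self.w)


def register_segment(seg: Segment) -> RegisteredCurve:
    """Affinely map a segment onto the unit square; endpoints are exact."""
    lm = seg.landmarks
    if lm.time_span <= 0:
        raise ValueError(
            f"segment {seg.waveform_id!r}: zero time span between landmarks "
            f"at {lm.a.time} ms and {lm.b.time} ms"
        )
    if lm.amplitude_span <= 0:
        raise ValueError(
            f"segment {seg.waveform_id!r}: degenerate landmark pair (a-wave "
            f"{lm.a.amplitude} µV, b-wave {lm.b.amplitude} µV) — no amplitude "
            "span to register"
        )
    u = (seg.times - lm.a.time) / lm.time_span
    w = (seg.amplitudes - lm.a.amplitude) / lm.amplitude_span
    # Endpoint arithmetic is exact in floating point: (x-x)/d == 0, d/d == 1.
    return RegisteredCurve(seg.waveform_id, u, w, lm, group=seg.group)


def resample_registered(reg: RegisteredCurve, m: int) -> np.ndarray:
    """Values of the polygonal registered curve on the uniform grid
    ``u_j = j/(m-1)``; the first value is 0 and the last is 1."""
    if m < 2:
        raise ValueError(f"registered grid needs at least 2 points, got {m}")
    grid = np.linspace(0.0, 1.0, int(m))
    return reg.curve().resample(grid)


@dataclass(frozen=True)
class RegisteredEnsemble:
    """Registered amplitudes of many waveforms on one shared unit grid."""

    grid: np.ndarray
    values: np.ndarray  # one row per waveform
    waveform_ids: tuple[str, ...]
    groups: tuple[str, ...]

    @property
    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_matrix(self, label: str) -> np.ndarray:
        mask = np.asarray([g == label for g in self.groups])
        if not mask.any():
            raise KeyError(f"no registered curves with group label {label!r}")
        return self.values[mask]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=list(self.waveform_ids))
        df.insert(0, "u", self.grid)
        return df


def register_cohort(segments: Sequence[Segment], m: int = DEFAULT_GRID_POINTS) -> RegisteredEnsemble:
    """Register a batch of segments and resample onto a shared unit grid.

    Degenerate segments (no amplitude span) are skipped with a warning;
    raises if every segment is degenerate or the batch is empty.
    """
    if not segments:
        raise ValueError("no segments to register")
    rows, ids, groups = [], [], []
    for seg in segments:
        if seg.is_degenerate:
            logger.warning(
                "skipping degenerate segment %r (no amplitude span)", seg.waveform_id
            )
            continue
        reg = register_segment(seg)
        rows.append(resample_registered(reg, m))
        ids.append(seg.waveform_id)
        groups.append(seg.group)
    if not rows:
        raise ValueError("every segment was degenerate; nothing to register")
    grid = np.linspace(0.0, 1.0, int(m))
    return RegisteredEnsemble(grid, np.vstack(rows), tuple(ids), tuple(groups))
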