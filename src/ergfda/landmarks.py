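"""Landmark detection: a-wave minimum, b-wave maximum, AL-b extraction.

The flash ERG shows a negative trough (a-wave) followed by a positive peak
(b-wave); the segment between the two — the ascending limb of the b-wave
(AL-b) — is the region of interest for registration.  Landmarks are located
by grid-sample argmin/argmax inside closed search windows, so every
landmark is an exact sample of its waveform and registration endpoints are
exact.  Ties are broken to the earliest time (the first trough/peak, the
usual clinical convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort, TimeWindow, Waveform

__all__ = [
    "DEFAULT_A_SEARCH",
    "DEFAULT_B_SEARCH",
    "TimeWindow",
    "Landmark",
    "LandmarkPair",
    "Segment",
    "LandmarkingResult",
    "find_a_wave_minimum",
    "find_b_wave_maximum",
    "extract_alb_segment",
    "landmark_cohort",
    "landmarks_table",
]

logger = logging.getLogger(__name__)

#: Default search window for the a-wave trough, ms.
DEFAULT_A_SEARCH = TimeWindow(5.0, 25.0)
#: Default search window for the b-wave peak, ms.  The effective window is
#: additionally restricted to times strictly after the a-wave minimum.
DEFAULT_B_SEARCH = TimeWindow(5.0, 60.0)


@dataclass(frozen=True)
class Landmark:
    """An actual sample of a waveform marking a physiological extremum."""

    time: float
    amplitude: float
    kind: str  # "a_min" or "b_max"

    def __post_init__(self) -> None:
        if self.kind not in ("a_min", "b_max"):
            raise ValueError(f"landmark kind must be 'a_min' or 'b_max', got {self.kind!r}")


@dataclass(frozen=True)
class LandmarkPair:
    """The a-wave minimum and b-wave maximum delimiting the AL-b segment.

    A pair with ``b.amplitude <= a.amplitude`` is *degenerate* (for example
    a flat trace); it is representable so batch processing can flag and
    skip it rather than abort.
    """

    a: Landmark
    b: Landmark

    def __post_init__(self) -> None:
        if self.a.kind != "a_min" or self.b.kind != "b_max":
            raise ValueError("LandmarkPair needs an a_min landmark and a b_max landmark")
        if not self.a.time < self.b.time:
            raise ValueError(
                f"a-wave minimum at {self.a.time} ms must precede the b-wave "
                f"maximum at {self.b.time} ms"
            )

    @property
    def is_degenerate(self) -> bool:
        return not self.b.amplitude > self.a.amplitude

    @property
    def time_span(self) -> float:
        return self.b.time - self.a.time

    @property
    def amplitude_span(self) -> float:
        return self.b.amplitude - self.a.amplitude


@dataclass(frozen=True)
class Segment:
    """The AL-b samples of one waveform, delimited by its landmark pair."""

    waveform_id: str
    times: np.ndarray
    amplitudes: np.ndarray
    landmarks: LandmarkPair
    group: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", v)
        lm = self.landmarks
        if t.size < 2:
            raise ValueError(f"segment {self.waveform_id!r}: needs at least 2 samples")
        if t[0] != lm.a.time or v[0] != lm.a.amplitude:
            raise ValueError(
                f"segment {self.waveform_id!r}: first sample must equal the "
                "a-wave landmark"
            )
        if t[-1] != lm.b.time or v[-1] != lm.b.amplitude:
            raise ValueError(
                f"segment {self.waveform_id!r}: last sample must equal the "
                "b-wave landmark"
            )
        if v.min() < lm.a.amplitude or v.max() > lm.b.amplitude:
            raise ValueError(
                f"segment {self.waveform_id!r}: landmark amplitudes must be the "
                "segment extrema"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.landmarks.is_degenerate


def _window_mask(w: Waveform, search: TimeWindow) -> np.ndarray:
    mask = (w.times >= search.start) & (w.times <= search.end)
    return mask


def find_a_wave_minimum(w: Waveform, search: TimeWindow = DEFAULT_A_SEARCH) -> Landmark:
    """Locate the a-wave trough: the minimal-amplitude sample in the closed
    search window, earliest time winning ties."""
    mask = _window_mask(w, search)
    if not mask.any():
        raise ValueError(
            f"waveform {w.waveform_id!r}: no samples in a-wave search window "
            f"[{search.start}, {search.end}] ms"
        )
    idx = np.flatnonzero(mask)
    j = idx[int(np.argmin(w.amplitudes[idx]))]  # argmin returns first minimum
    return Landmark(float(w.times[j]), float(w.amplitudes[j]), "a_min")


def find_b_wave_maximum(
    w: Waveform,
    search: TimeWindow = DEFAULT_B_SEARCH,
    *,
    after: Landmark,
) -> Landmark:
    """Locate the b-wave peak: the maximal-amplitude sample in the closed
    search window restricted to times strictly after ``after`` (the a-wave
    minimum), earliest time winning ties."""
    if not search.end > after.time:
        raise ValueError(
            f"b-wave search window ends at {search.end} ms, before the a-wave "
            f"minimum at {after.time} ms"
        )
    mask = _window_mask(w, search) & (w.times > after.time)
    if not mask.any():
        raise ValueError(
            f"waveform {w.waveform_id!r}: no samples after the a-wave minimum "
            f"({after.time} ms) in b-wave search window "
            f"[{search.start}, {search.end}] ms"
        )
    idx = np.flatnonzero(mask)
    j = idx[int(np.argmax(w.amplitudes[idx]))]
    return Landmark(float(w.times[j]), float(w.amplitudes[j]), "b_max")


def extract_alb_segment(w: Waveform, pair: LandmarkPair) -> Segment:
    """Slice the samples with a.time <= t <= b.time; endpoints are exactly
    the landmarks."""
    for lm in (pair.a, pair.b):
        hits = np.flatnonzero(w.times == lm.time)
        if hits.size != 1 or w.amplitudes[hits[0]] != lm.amplitude:
            raise ValueError(
                f"landmark at ({lm.time} ms, {lm.amplitude} µV) is not a sample "
                f"of waveform {w.waveform_id!r}"
            )
    mask = (w.times >= pair.a.time) & (w.times <= pair.b.time)
    return Segment(
        waveform_id=w.waveform_id,
        times=w.times[mask],
        amplitudes=w.amplitudes[mask],
        landmarks=pair,
        group=w.group,
        participant_id=w.participant_id,
    )


@dataclass(frozen=True)
class LandmarkingResult:
    """Batch landmarking output: per-waveform segments plus failure notes.

    ``failures`` maps waveform_id to the error message for waveforms whose
    landmarks could not be located; degenerate segments (flat traces where
    the b amplitude does not exceed the a amplitude) appear in ``segments``
    with ``is_degenerate`` set and are listed in ``degenerate_ids``.
    """

    segments: tuple[Segment, ...]
    failures: dict[str, str]

    @property
    def degenerate_ids(self) -> list[str]:
        return [s.waveform_id for s in self.segments if s.is_degenerate]

    @property
    def usable_segments(self) -> list[Segment]:
        return [s for s in self.segments if not s.is_degenerate]


def landmark_cohort(
    cohort: Cohort,
    a_search: TimeWindow = DEFAULT_A_SEARCH,
    b_search: TimeWindow = DEFAULT_B_SEARCH,
) -> LandmarkingResult:
    """Landmark every waveform; collect per-waveform failures instead of
    aborting the batch.  Raises only if the cohort is empty or every
    waveform fails."""
    if not cohort.waveforms:
        raise ValueError("empty cohort")
    segments: list[Segment] = []
    failures: dict[str, str] = {}
    for w in cohort:
        try:
            a = find_a_wave_minimum(w, a_search)
            b = find_b_wave_maximum(w, b_search, after=a)
            seg = extract_alb_segment(w, LandmarkPair(a, b))
        except ValueError as exc:
            failures[w.waveform_id] = str(exc)
            logger.warning("landmarking failed for %r: %s", w.waveform_id, exc)
            continue
        if seg.is_degenerate:
            logger.warning(
                "waveform %r is degenerate (b-wave amplitude %.6g does not "
                "exceed a-wave amplitude %.6g); excluded from registration",
                w.waveform_id,
                b.amplitude,
                a.amplitude,
            )
        segments.append(seg)
    if not segments:
        details = "; ".join(f"{k}: {v}" for k, v in failures.items())
        raise ValueError(f"landmarking failed for every waveform ({details})")
    return LandmarkingResult(tuple(segments), failures)


def landmarks_table(result: LandmarkingResult) -> pd.DataFrame:
    """Tabulate landmarks as waveform_id,a_time_ms,a_uv,b_time_ms,b_uv."""
    rows = [
        {
            "waveform_id": s.waveform_id,
            "a_time_ms": s.landmarks.a.time,
            "a_uv": s.landmarks.a.amplitude,
            "b_time_ms": s.landmarks.b.time,
            "b_uv": s.landmarks.b.amplitude,
            "degenerate": s.is_degenerate,
        }
        for s in result.segments
    ]
    return pd.DataFrame(rows)
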