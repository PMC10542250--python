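"""Cohort I/O for discretely sampled ERG waveforms.

A cohort is stored as two CSV files:

* a **wide waveform CSV** whose first column is ``time_ms`` (the shared
  sampling grid, strictly increasing) and whose remaining columns are one
  amplitude trace (µV) per waveform, headed by the waveform id;
* a **metadata CSV** with columns ``waveform_id,participant_id,group,eye``
  (``eye`` is one of ``right``, ``left``, ``unknown``).

Times are milliseconds and amplitudes microvolts throughout; no unit
conversion is attempted.  Missing cells are rejected rather than imputed,
because every downstream statistic is computed time-pointwise across
complete curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VALID_EYES",
    "TimeWindow",
    "Waveform",
    "Cohort",
    "read_cohort",
    "read_cohort_long",
    "write_cohort",
    "restrict_to_window",
]

logger = logging.getLogger(__name__)

VALID_EYES = ("right", "left", "unknown")

_META_COLUMNS = ["waveform_id", "participant_id", "group", "eye"]


@dataclass(frozen=True)
class TimeWindow:
    """A closed time interval [start, end] in milliseconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start) and np.isfinite(self.end)):
            raise ValueError("TimeWindow bounds must be finite")
        if not self.start < self.end:
            raise ValueError(
                f"TimeWindow start must be < end (got {self.start} >= {self.end})"
            )

    def contains(self, t: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(t) >= self.start) & (np.asarray(t) <= self.end)


@dataclass(frozen=True)
class Waveform:
    """One recorded ERG trace plus its metadata.

    ``times`` (ms) must be strictly increasing and ``amplitudes`` (µV) the
    same length; both must be finite with at least two samples.
    """

    waveform_id: str
    participant_id: str
    group: str
    eye: str
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", v)
        if self.eye not in VALID_EYES:
            raise ValueError(
                f"waveform {self.waveform_id!r}: eye must be one of {VALID_EYES}, "
                f"got {self.eye!r}"
            )
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ValueError(
                f"waveform {self.waveform_id!r}: times and amplitudes must be "
                "1-D arrays of equal length"
            )
        if t.size < 2:
            raise ValueError(
                f"waveform {self.waveform_id!r}: needs at least 2 samples, got {t.size}"
            )
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError(
                f"waveform {self.waveform_id!r}: times and amplitudes must be finite"
            )
        if not np.all(np.diff(t) > 0):
            bad = int(np.argmin(np.diff(t) > 0))
            raise ValueError(
                f"waveform {self.waveform_id!r}: sample times must be strictly "
                f"increasing (violated at sample index {bad + 1})"
            )

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) sample time in ms."""
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class Cohort:
    """A collection of waveforms, optionally sharing a common time grid."""

    waveforms: tuple[Waveform, ...]
    common_grid: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "waveforms", tuple(self.waveforms))
        ids = [w.waveform_id for w in self.waveforms]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate waveform_ids in cohort: {dupes}")
        if self.common_grid is not None:
            grid = np.asarray(self.common_grid, dtype=float)
            object.__setattr__(self, "common_grid", grid)
            for w in self.waveforms:
                if w.times.shape != grid.shape or not np.array_equal(w.times, grid):
                    raise ValueError(
                        f"waveform {w.waveform_id!r} is not on the declared "
                        "common grid"
                    )

    def __len__(self) -> int:
        return len(self.waveforms)

    def __iter__(self):
        return iter(self.waveforms)

    @property
    def waveform_ids(self) -> list[str]:
        return [w.waveform_id for w in self.waveforms]

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for w in self.waveforms:
            seen.setdefault(w.group, None)
        return list(seen)

    def by_group(self, label: str) -> "Cohort":
        sub = tuple(w for w in self.waveforms if w.group == label)
        if not sub:
            raise KeyError(f"no waveforms with group label {label!r}")
        return Cohort(sub, self.common_grid)

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (grid, amplitudes) with one row per waveform.

        Requires a common grid (the "across individuals" axis of every
        pointwise statistic).
        """
        if self.common_grid is None:
            raise ValueError(
                "cohort has no common grid; resample waveforms first"
            )
        if not self.waveforms:
            raise ValueError("empty cohort")
        return self.common_grid, np.vstack([w.amplitudes for w in self.waveforms])


def _parse_metadata(metadata_file) -> pd.DataFrame:
    meta = pd.read_csv(metadata_file, dtype=str)
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(
            f"metadata file {metadata_file}: missing column(s) {missing}; "
            f"expected header {','.join(_META_COLUMNS)}"
        )
    if meta["waveform_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["waveform_id"].duplicated(), "waveform_id"])
        raise ValueError(f"metadata file {metadata_file}: duplicate waveform_id rows {dupes}")
    bad_eye = ~meta["eye"].isin(VALID_EYES)
    if bad_eye.any():
        row = int(np.argmax(bad_eye.to_numpy()))
        raise ValueError(
            f"metadata file {metadata_file}: row {row + 2} has eye="
            f"{meta['eye'].iloc[row]!r}; must be one of {VALID_EYES}"
        )
    return meta.set_index("waveform_id")


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    empty = raw.isna()
    if empty.any():
        row = int(np.argmax(empty.to_numpy()))
        raise ValueError(
            f"waveform file {path}: empty cell in column {col!r}, data row {row + 1}"
        )
    try:
        # numpy's string->double conversion is round-trip exact, unlike
        # pandas' fast to_numeric parser
        return raw.to_numpy(dtype=float)
    except (ValueError, TypeError):
        for row, cell in enumerate(raw):
            try:
                float(cell)
            except (ValueError, TypeError):
                raise ValueError(
                    f"waveform file {path}: non-numeric cell {cell!r} in column "
                    f"{col!r}, data row {row + 1}"
                ) from None
        raise


def read_cohort(waveform_file, metadata_file) -> Cohort:
    """Read a cohort from a wide waveform CSV and its metadata CSV.

    Every amplitude column must have a matching metadata row; the shared
    time column becomes the cohort's ``common_grid``.
    """
    df = pd.read_csv(waveform_file, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(
            f"waveform file {waveform_file}: need a time column plus at least "
            "one waveform column"
        )
    if df.columns[0] != "time_ms":
        raise ValueError(
            f"waveform file {waveform_file}: first column must be 'time_ms', "
            f"got {df.columns[0]!r}"
        )
    times = _numeric_column(df, "time_ms", waveform_file)
    increasing = np.diff(times) > 0
    if not np.all(increasing):
        row = int(np.argmin(increasing))
        raise ValueError(
            f"waveform file {waveform_file}: time_ms not strictly increasing "
            f"at data row {row + 2}"
        )
    meta = _parse_metadata(metadata_file)

    waveforms = []
    for col in df.columns[1:]:
        if col not in meta.index:
            raise ValueError(
                f"waveform column {col!r} has no metadata row in {metadata_file}"
            )
        row = meta.loc[col]
        waveforms.append(
            Waveform(
                waveform_id=col,
                participant_id=str(row["participant_id"]),
                group=str(row["group"]),
                eye=str(row["eye"]),
                times=times,
                amplitudes=_numeric_column(df, col, waveform_file),
            )
        )
    unused = set(meta.index) - set(df.columns[1:])
    if unused:
        logger.warning(
            "metadata rows without a waveform column ignored: %s", sorted(unused)
        )
    return Cohort(tuple(waveforms), common_grid=times)


def read_cohort_long(long_file, metadata_file) -> Cohort:
    """Convenience alias for long-format data.

    ``long_file`` has columns ``waveform_id,time_ms,amplitude_uv``; all
    waveforms must share the same time grid (the long table is pivoted to
    the wide layout and validated the same way).
    """
    df = pd.read_csv(long_file)
    needed = ["waveform_id", "time_ms", "amplitude_uv"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"long file {long_file}: missing column(s) {missing}")
    wide = df.pivot(index="time_ms", columns="waveform_id", values="amplitude_uv")
    if wide.isna().any().any():
        raise ValueError(
            f"long file {long_file}: waveforms do not share a common time grid"
        )
    meta = _parse_metadata(metadata_file)
    grid = wide.index.to_numpy(dtype=float)
    waveforms = []
    for col in wide.columns:
        if col not in meta.index:
            raise ValueError(
                f"waveform {col!r} has no metadata row in {metadata_file}"
            )
        row = meta.loc[col]
        waveforms.append(
            Waveform(
                waveform_id=str(col),
                participant_id=str(row["participant_id"]),
                group=str(row["group"]),
                eye=str(row["eye"]),
                times=grid,
                amplitudes=wide[col].to_numpy(dtype=float),
            )
        )
    return Cohort(tuple(waveforms), common_grid=grid)


def write_cohort(cohort: Cohort, waveform_file, metadata_file) -> None:
    """Write a common-grid cohort back to the wide CSV pair.

    Round-trips through :func:`read_cohort` reproduce amplitudes exactly
    (full ``repr`` precision is written).
    """
    if not cohort.waveforms:
        raise ValueError("refusing to write an empty cohort")
    if cohort.common_grid is None:
        raise ValueError(
            "cohort has no common grid; resample waveforms onto a shared grid "
            "before writing"
        )
    data = {"time_ms": cohort.common_grid}
    for w in cohort.waveforms:
        data[w.waveform_id] = w.amplitudes
    pd.DataFrame(data).to_csv(waveform_file, index=False)
    meta = pd.DataFrame(
        {
            "waveform_id": cohort.waveform_ids,
            "participant_id": [w.participant_id for w in cohort.waveforms],
            "group": [w.group for w in cohort.waveforms],
            "eye": [w.eye for w in cohort.waveforms],
        }
    )
    meta.to_csv(metadata_file, index=False)


def restrict_to_window(cohort: Cohort, window: TimeWindow) -> Cohort:
    """Keep only samples with time in the closed interval [start, end].

    The printed display bounds (e.g. 9.55–34.9 ms) are treated as
    inclusive.  Metadata is untouched; sample order is preserved.
    """
    if not cohort.waveforms:
        raise ValueError("empty cohort")
    new_waves = []
    for w in cohort.waveforms:
        lo, hi = w.span
        if window.start < lo or window.end > hi:
            raise ValueError(
                f"window [{window.start}, {window.end}] ms outside the span of "
                f"waveform {w.waveform_id!r} (available: [{lo}, {hi}] ms)"
            )
        mask = window.contains(w.times)
        if int(np.count_nonzero(mask)) < 2:
            raise ValueError(
                f"window [{window.start}, {window.end}] ms retains fewer than 2 "
                f"samples of waveform {w.waveform_id!r}"
            )
        new_waves.append(
            replace(w, times=w.times[mask], amplitudes=w.amplitudes[mask])
        )
    grid = None
    if cohort.common_grid is not None:
        mask = window.contains(cohort.common_grid)
        grid = cohort.common_grid[mask]
    return Cohort(tuple(new_waves), common_grid=grid)
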