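"""Core CGM/event data types and CSV input-output.

Glucose traces are kept on a uniform sampling grid (5 min by default) with
missing samples stored as NaN ("blanks").  Event logs are ordered sequences of
(timestamp, label) pairs, with labels drawn from the five event classes that
drive the partitioning of the trace: the three meals, the night period and
hypoglycemia-treatment episodes.

All numeric modules downstream work with integer sample offsets from a series
epoch; calendar timestamps only exist at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GlucoseSeries",
    "EventLog",
    "DataFormatError",
    "LABELS",
    "read_cgm_csv",
    "write_cgm_csv",
    "read_events_csv",
    "write_events_csv",
]

#: canonical event labels
BREAKFAST = "Breakfast"
LUNCH = "Lunch"
DINNER = "Dinner"
NIGHT = "Night"
HYPO_TREATMENT = "HypoTreatment"
LABELS = (BREAKFAST, LUNCH, DINNER, NIGHT, HYPO_TREATMENT)
MEAL_LABELS = (BREAKFAST, LUNCH, DINNER)

_LABEL_ALIASES = {
    "breakfast": BREAKFAST,
    "lunch": LUNCH,
    "dinner": DINNER,
    "night": NIGHT,
    "hypotreatment": HYPO_TREATMENT,
    "hypo treatment": HYPO_TREATMENT,
    "hypo_treatment": HYPO_TREATMENT,
    "hypoglycemia treatment": HYPO_TREATMENT,
    "hypoglycemia_treatment": HYPO_TREATMENT,
}

GLUCOSE_MIN = 20.0  # mg/dL, physical plausibility bounds for non-blank samples
GLUCOSE_MAX = 600.0


class DataFormatError(ValueError):
    """Raised for malformed CGM/event files or invalid series content."""


def canonical_label(raw: str) -> str:
    """Map a free-form label string onto the canonical label set."""
    key = str(raw).strip().lower()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise DataFormatError(f"unknown label: {raw!r}") from None


def snap_offset(delta_minutes: float, period: float) -> int:
    """Nearest-grid-point rounding with ties broken toward the earlier sample."""
    return int(math.ceil(delta_minutes / period - 0.5))


@dataclasses.dataclass
class GlucoseSeries:
    """Uniformly sampled CGM trace, glucose in mg/dL, blanks as NaN.

    Sample ``k`` is taken at ``start_time + k * sampling_period`` minutes.
    """

    start_time: pd.Timestamp
    values: np.ndarray
    sampling_period: int = 5  # minutes

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataFormatError("values must be one-dimensional")
        if self.sampling_period <= 0:
            raise DataFormatError("sampling_period must be positive")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (
            observed.min() < GLUCOSE_MIN or observed.max() > GLUCOSE_MAX
        ):
            raise DataFormatError(
                f"glucose values outside [{GLUCOSE_MIN}, {GLUCOSE_MAX}] mg/dL"
            )

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, offset):
        return self.values[offset]

    def timestamp(self, offset: int) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(minutes=offset * self.sampling_period)

    def offset_of(self, ts: pd.Timestamp) -> int:
        """Sample offset of the grid point nearest to ``ts`` (ties earlier)."""
        delta = (pd.Timestamp(ts) - self.start_time).total_seconds() / 60.0
        return snap_offset(delta, self.sampling_period)

    def equals(self, other: "GlucoseSeries") -> bool:
        return (
            self.start_time == other.start_time
            and self.sampling_period == other.sampling_period
            and self.values.size == other.values.size
            and bool(np.array_equal(self.values, other.values, equal_nan=True))
        )


@dataclasses.dataclass
class EventLog:
    """Ordered sequence of time-stamped labeled events."""

    times: list
    labels: list

    def __post_init__(self) -> None:
        self.times = [pd.Timestamp(t) for t in self.times]
        self.labels = [canonical_label(l) for l in self.labels]
        if len(self.times) != len(self.labels):
            raise DataFormatError("times and labels length mismatch")
        for a, b in zip(self.times, self.times[1:]):
            if not a < b:
                raise DataFormatError("event timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[tuple]:
        return iter(zip(self.times, self.labels))

    def to_offsets(self, series: GlucoseSeries) -> np.ndarray:
        """Event offsets on the series grid; events must fall inside the series."""
        offs = np.array([series.offset_of(t) for t in self.times], dtype=int)
        if len(offs) and (offs.min() < 0 or offs.max() >= len(series)):
            raise DataFormatError("event timestamp outside the CGM series range")
        if len(offs) > 1 and np.any(np.diff(offs) <= 0):
            raise DataFormatError("events collapse onto the same grid sample")
        return offs

    def equals(self, other: "EventLog") -> bool:
        return self.times == other.times and self.labels == other.labels


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_BLANK_TOKENS = {"", "na", "nan"}


def _parse_glucose(cell) -> float:
    if cell is None:
        return np.nan
    text = str(cell).strip()
    if text.lower() in _BLANK_TOKENS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise DataFormatError(f"unparseable glucose value: {cell!r}") from None


def read_cgm_csv(path, sampling_period: int = 5) -> GlucoseSeries:
    """Read ``timestamp,glucose_mgdl`` rows into a grid-aligned series.

    Rows are snapped to the nearest grid point anchored at the first
    timestamp; interior gaps become blanks.  Two rows snapping to the same
    grid point, or out-of-order timestamps, are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected two columns (timestamp, glucose)")
    if df.shape[0] == 0:
        raise DataFormatError(f"{path}: empty CGM file")
    try:
        stamps = pd.to_datetime(df.iloc[:, 0])
    except (ValueError, TypeError) as exc:
        raise DataFormatError(f"{path}: unparseable timestamps: {exc}") from None
    if not stamps.is_monotonic_increasing or stamps.duplicated().any():
        raise DataFormatError(f"{path}: timestamps must be strictly increasing")
    start = pd.Timestamp(stamps.iloc[0])
    deltas = (stamps - start).dt.total_seconds() / 60.0
    offsets = np.array([snap_offset(d, sampling_period) for d in deltas], dtype=int)
    if np.any(np.diff(offsets) <= 0):
        raise DataFormatError(f"{path}: two rows snap to the same grid point")
    values = np.full(offsets[-1] + 1, np.nan)
    glucose = [_parse_glucose(v) for v in df.iloc[:, 1]]
    values[offsets] = glucose
    return GlucoseSeries(start, values, sampling_period)


def _format_value(v: float) -> str:
    if np.isnan(v):
        return ""
    return repr(float(v))


def write_cgm_csv(series: GlucoseSeries, path) -> None:
    """Write a series so that :func:`read_cgm_csv` round-trips it exactly."""
    if len(series) == 0:
        raise DataFormatError("refusing to write an empty series")
    lines = ["timestamp,glucose_mgdl"]
    for k in range(len(series)):
        lines.append(f"{series.timestamp(k).isoformat()},{_format_value(series.values[k])}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_events_csv(path, sampling_period: int = 5, grid_epoch=None) -> EventLog:
    """Read ``timestamp,label`` rows; labels case-insensitive; rows sorted.

    Timestamps are snapped to the CGM grid convention (nearest multiple of
    the sampling period from ``grid_epoch``, default the day start of the
    first event).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DataFormatError(f"{path}: expected two columns (timestamp, label)")
    if df.shape[0] == 0:
        raise DataFormatError(f"{path}: empty event file")
    try:
        stamps = pd.to_datetime(df.iloc[:, 0])
    except (ValueError, TypeError) as exc:
        raise DataFormatError(f"{path}: unparseable timestamps: {exc}") from None
    labels = []
    for idx, raw in enumerate(df.iloc[:, 1]):
        try:
            labels.append(canonical_label(raw))
        except DataFormatError:
            raise DataFormatError(f"{path}: row {idx + 1}: unknown label {raw!r}") from None
    order = np.argsort(stamps.values, kind="stable")
    stamps = stamps.iloc[order].reset_index(drop=True)
    labels = [labels[i] for i in order]
    epoch = pd.Timestamp(grid_epoch) if grid_epoch is not None else stamps.iloc[0].normalize()
    snapped = []
    for ts in stamps:
        k = snap_offset((ts - epoch).total_seconds() / 60.0, sampling_period)
        snapped.append(epoch + pd.Timedelta(minutes=k * sampling_period))
    for a, b in zip(snapped, snapped[1:]):
        if a == b:
            raise DataFormatError(f"{path}: two events snap to the same grid point")
    return EventLog(snapped, labels)


def write_events_csv(log: EventLog, path) -> None:
    if len(log) == 0:
        raise DataFormatError("refusing to write an empty event log")
    lines = ["timestamp,label"]
    for ts, label in log:
        lines.append(f"{ts.isoformat()},{label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
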