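"""Event-to-event partitioning of CGM data and length regularization.

Each event opens a subseries that runs up to the next event (the last event's
subseries runs to the end of the trace).  Subseries are grouped into three
partitions — meals (M), night (N) and hypoglycemia treatment (H) — by the
label of their *starting* event, then padded with trailing blanks to the
partition's maximum length so that an artificial seasonality can be enforced
downstream.  Each subseries also carries ``Pr`` pre-samples: the CGM samples
immediately preceding the event onset, needed to feed autoregressive terms at
the start of the event.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    DINNER,
    HYPO_TREATMENT,
    MEAL_LABELS,
    NIGHT,
    DataFormatError,
    EventLog,
    GlucoseSeries,
)

__all__ = [
    "Subseries",
    "RegularizedPartition",
    "PARTITION_KEYS",
    "group_of",
    "build_partitions",
    "regularize",
    "add_night_events",
]

PARTITION_KEYS = ("M", "N", "H")

_GROUPS = {label: "M" for label in MEAL_LABELS}
_GROUPS[NIGHT] = "N"
_GROUPS[HYPO_TREATMENT] = "H"

DEFAULT_PRESAMPLE = 5  # samples of pre-event data fed to the AR terms


def group_of(label: str) -> str:
    """Partition key ('M', 'N' or 'H') of an event label."""
    return _GROUPS[label]


@dataclasses.dataclass
class Subseries:
    """One event-to-event glucose segment plus its pre-sampling data."""

    event_index: int
    start_offset: int
    end_offset: int
    values: np.ndarray
    presample: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.presample = np.asarray(self.presample, dtype=float)
        if self.end_offset - self.start_offset != self.values.size:
            raise ValueError("subseries length inconsistent with its offsets")
        if self.values.size < 1:
            raise ValueError("subseries must contain at least one sample")

    @property
    def length(self) -> int:
        return self.values.size


@dataclasses.dataclass
class RegularizedPartition:
    """Blank-padded matrix of subseries plus the pre-sampling block."""

    key: str
    L: int
    Pr: int
    rows: np.ndarray        # (n, L), trailing blanks as NaN
    presamples: np.ndarray  # (n, Pr)
    event_indices: list
    lengths: list

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.presamples = np.asarray(self.presamples, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != self.L:
            raise ValueError("rows must be an (n, L) matrix")
        if self.rows.shape[0] < 1:
            raise ValueError("a partition needs at least one subseries")
        if self.presamples.shape != (self.rows.shape[0], self.Pr):
            raise ValueError("presamples must be an (n, Pr) block")

    @property
    def n(self) -> int:
        return self.rows.shape[0]


def _presample_of(series: GlucoseSeries, start: int, pr: int) -> np.ndarray:
    """``pr`` samples before ``start``, left-padded with blanks if short."""
    lo = max(0, start - pr)
    chunk = series.values[lo:start]
    if chunk.size < pr:
        chunk = np.concatenate([np.full(pr - chunk.size, np.nan), chunk])
    return chunk


def build_partitions(
    series: GlucoseSeries,
    log: EventLog,
    pr: int = DEFAULT_PRESAMPLE,
    min_length: int = 2,
) -> dict:
    """Split a CGM trace into the M/N/H subseries lists.

    Subseries ``i`` spans ``[te_i, te_{i+1})`` and is assigned to the group of
    its starting event; the final event's segment runs to the series end.
    Subseries shorter than ``min_length`` samples are dropped with a warning.
    """
    if len(log) < 2:
        raise DataFormatError("need at least two events to build partitions")
    offsets = log.to_offsets(series)
    bounds = list(offsets) + [len(series)]
    out = {key: [] for key in PARTITION_KEYS}
    for i, label in enumerate(log.labels):
        start, end = bounds[i], bounds[i + 1]
        if end - start < min_length:
            warnings.warn(
                f"dropping subseries at event {i} ({label}): "
                f"length {end - start} < {min_length}",
                stacklevel=2,
            )
            continue
        sub = Subseries(
            event_index=i,
            start_offset=start,
            end_offset=end,
            values=series.values[start:end].copy(),
            presample=_presample_of(series, start, pr),
            label=label,
        )
        out[group_of(label)].append(sub)
    return out


def regularize(subseries: list, key: str, pr: int = DEFAULT_PRESAMPLE) -> RegularizedPartition:
    """Pad subseries with trailing blanks to the partition's maximum length."""
    if not subseries:
        raise DataFormatError(f"partition {key!r} is empty, cannot regularize")
    L = max(s.length for s in subseries)
    n = len(subseries)
    rows = np.full((n, L), np.nan)
    pres = np.empty((n, pr))
    for j, s in enumerate(subseries):
        rows[j, : s.length] = s.values
        if s.presample.size != pr:
            raise DataFormatError("subseries presample length does not match Pr")
        pres[j] = s.presample
    return RegularizedPartition(
        key=key,
        L=L,
        Pr=pr,
        rows=rows,
        presamples=pres,
        event_indices=[s.event_index for s in subseries],
        lengths=[s.length for s in subseries],
    )


def add_night_events(log: EventLog, night_delay_hours: float = 6.0) -> EventLog:
    """Synthesize Night events at Dinner + ``night_delay_hours`` when absent."""
    if NIGHT in log.labels:
        return log
    times = list(log.times)
    labels = list(log.labels)
    for ts, label in zip(log.times, log.labels):
        if label == DINNER:
            times.append(ts + pd.Timedelta(hours=night_delay_hours))
            labels.append(NIGHT)
    order = np.argsort(pd.to_datetime(times).values, kind="stable")
    return EventLog([times[i] for i in order], [labels[i] for i in order])


# ---------------------------------------------------------------------------
# Partition dump format: one CSV per group + JSON sidecar {key, L, Pr, n}
# ---------------------------------------------------------------------------

def dump_partition(part: RegularizedPartition, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    lines = ["event_index,row_position,value"]
    for j in range(part.n):
        for k in range(part.L):
            v = part.rows[j, k]
            cell = "" if np.isnan(v) else repr(float(v))
            lines.append(f"{part.event_indices[j]},{k},{cell}")
    csv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    Path(sidecar_path).write_text(
        json.dumps({"key": part.key, "L": part.L, "Pr": part.Pr, "n": part.n}),
        encoding="utf-8",
    )
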