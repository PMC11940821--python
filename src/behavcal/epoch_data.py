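"""Data model and I/O for epoch-count time series and observation protocols.

An actigraph channel is a vector of activity counts, one per fixed-length
epoch (30 s by default).  During calibration an observer records the start
and stop time of each directed behaviour with a stopwatch; those intervals
are matched against the count time series to extract behaviour-labelled
epochs, which are then pooled ("concatenated") across children.

In-memory conventions
---------------------
* Timestamps are ISO-8601 strings in files and :class:`pandas.Timestamp`
  objects in memory; epoch *i* of a series spans
  ``[start + i*epoch_seconds, start + (i+1)*epoch_seconds)``.
* Observation intervals are half-open ``[start, stop)`` and an epoch is
  labelled only when its full span lies inside the interval.  This is
  conservative with respect to observer timing error and guarantees an
  epoch is never labelled twice.
* Labelled counts are a tidy :class:`pandas.DataFrame` with columns
  ``child_id, device, position, behaviour, epoch_index, count``
  (``LABELED_COLUMNS``); ``epoch_index`` is the time order of the epoch
  within its (child, device, position, behaviour) cell, which lets
  downstream code align paired channels without relying on row order.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .behaviours import (
    Behaviour,
    Device,
    Position,
    coerce_behaviour,
    coerce_device,
    coerce_position,
)
from .errors import FormatError, ValidationError

#: Column order of a labelled-counts frame.
LABELED_COLUMNS = ("child_id", "device", "position", "behaviour", "epoch_index", "count")

EPOCH_CSV_COLUMNS = ("child_id", "device", "position", "timestamp", "count")
PROTOCOL_CSV_COLUMNS = ("child_id", "behaviour", "start", "stop")


@dataclasses.dataclass
class EpochSeries:
    """One channel's count-per-epoch vector with device/position metadata."""

    child_id: str
    device: Device
    position: Position
    start_time: pd.Timestamp
    counts: np.ndarray
    epoch_seconds: float = 30.0

    def __post_init__(self) -> None:
        self.device = coerce_device(self.device)
        self.position = coerce_position(self.position)
        self.start_time = pd.Timestamp(self.start_time)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValidationError("counts must be a 1-D vector")
        if self.epoch_seconds <= 0:
            raise ValidationError("epoch_seconds must be positive")
        neg = np.flatnonzero(self.counts < 0)
        if neg.size:
            raise ValidationError(f"negative count at epoch {int(neg[0])}")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def epoch_starts(self) -> np.ndarray:
        """Epoch start offsets in seconds since ``start_time``."""
        return np.arange(len(self.counts)) * float(self.epoch_seconds)

    def timestamps(self) -> pd.DatetimeIndex:
        """Absolute start timestamp of every epoch."""
        return self.start_time + pd.to_timedelta(self.epoch_starts, unit="s")


@dataclasses.dataclass(frozen=True)
class ProtocolRecord:
    """One observed behaviour interval for one child, half-open [start, stop)."""

    child_id: str
    behaviour: Behaviour
    start: pd.Timestamp
    stop: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "behaviour", coerce_behaviour(self.behaviour))
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "stop", pd.Timestamp(self.stop))
        if self.stop <= self.start:
            raise ValidationError(
                f"protocol interval for {self.child_id}/{self.behaviour.value}: "
                f"stop ({self.stop}) must be after start ({self.start})"
            )


@dataclasses.dataclass
class BehaviourProtocol:
    """Observed start/stop intervals, validated for within-child overlap."""

    records: list[ProtocolRecord]

    def __post_init__(self) -> None:
        by_child: dict[str, list[ProtocolRecord]] = {}
        for rec in self.records:
            by_child.setdefault(rec.child_id, []).append(rec)
        for child, recs in by_child.items():
            recs = sorted(recs, key=lambda r: r.start)
            for a, b in zip(recs, recs[1:]):
                if b.start < a.stop:
                    raise ValidationError(
                        f"overlapping protocol intervals for child {child}: "
                        f"{a.behaviour.value} and {b.behaviour.value}"
                    )

    def for_child(self, child_id: str) -> list[ProtocolRecord]:
        return [r for r in self.records if r.child_id == child_id]

    def __len__(self) -> int:
        return len(self.records)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_epoch_csv(path: str | Path) -> list[EpochSeries]:
    """Read an epoch-count CSV into one :class:`EpochSeries` per channel.

    The file must have header ``child_id,device,position,timestamp,count``.
    Rows are grouped by (child_id, device, position) and ordered by
    timestamp within each group; the epoch length is inferred from the
    timestamp spacing (30 s when a group has a single row).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"child_id": str})
    _require_columns(df, EPOCH_CSV_COLUMNS, path)
    if df.empty:
        return []
    counts = pd.to_numeric(df["count"], errors="raise")
    neg = np.flatnonzero(counts.to_numpy() < 0)
    if neg.size:
        raise ValidationError(f"{path}: negative count at data row {int(neg[0])}")
    df = df.assign(count=counts, timestamp=pd.to_datetime(df["timestamp"]))

    out: list[EpochSeries] = []
    for (child, device, position), grp in df.groupby(
        ["child_id", "device", "position"], sort=True
    ):
        grp = grp.sort_values("timestamp", kind="stable")
        ts = grp["timestamp"].to_numpy()
        if len(ts) > 1:
            steps = np.diff(ts) / np.timedelta64(1, "s")
            epoch_seconds = float(np.median(steps))
        else:
            epoch_seconds = 30.0
        out.append(
            EpochSeries(
                child_id=str(child),
                device=device,
                position=position,
                start_time=grp["timestamp"].iloc[0],
                counts=grp["count"].to_numpy(dtype=float),
                epoch_seconds=epoch_seconds,
            )
        )
    return out


def write_epoch_csv(series: Iterable[EpochSeries], path: str | Path) -> None:
    """Write series to CSV so that :func:`read_epoch_csv` round-trips them."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "child_id": s.child_id,
                    "device": s.device.value,
                    "position": s.position.value,
                    "timestamp": s.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
                    "count": s.counts,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(EPOCH_CSV_COLUMNS))
    df.to_csv(path, index=False)


def read_protocol_csv(path: str | Path) -> BehaviourProtocol:
    """Read an observation protocol CSV (``child_id,behaviour,start,stop``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"child_id": str})
    _require_columns(df, PROTOCOL_CSV_COLUMNS, path)
    records = [
        ProtocolRecord(
            child_id=str(row.child_id),
            behaviour=coerce_behaviour(row.behaviour),
            start=pd.Timestamp(row.start),
            stop=pd.Timestamp(row.stop),
        )
        for row in df.itertuples(index=False)
    ]
    return BehaviourProtocol(records=records)


def write_protocol_csv(protocol: BehaviourProtocol, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "child_id": [r.child_id for r in protocol.records],
            "behaviour": [r.behaviour.value for r in protocol.records],
            "start": [r.start.strftime("%Y-%m-%dT%H:%M:%S") for r in protocol.records],
            "stop": [r.stop.strftime("%Y-%m-%dT%H:%M:%S") for r in protocol.records],
        }
    )
    df.to_csv(path, index=False)


def empty_labeled() -> pd.DataFrame:
    """An empty labelled-counts frame with canonical columns."""
    return pd.DataFrame(
        {
            "child_id": pd.Series(dtype=str),
            "device": pd.Series(dtype=object),
            "position": pd.Series(dtype=object),
            "behaviour": pd.Series(dtype=object),
            "epoch_index": pd.Series(dtype=int),
            "count": pd.Series(dtype=float),
        }
    )


def extract_segments(series: EpochSeries, protocol: BehaviourProtocol) -> pd.DataFrame:
    """Label epochs of one series from the observation protocol.

    An epoch is assigned a behaviour iff its full ``[epoch_start, epoch_end)``
    span lies within the behaviour's observed ``[start, stop)`` interval.
    Epochs covered by no interval are dropped.  A protocol interval that
    yields no epochs (e.g. lies outside the recorded range) raises a
    warning and contributes zero rows.
    """
    rows: list[pd.DataFrame] = []
    starts = series.start_time + pd.to_timedelta(series.epoch_starts, unit="s")
    ends = starts + pd.Timedelta(seconds=float(series.epoch_seconds))
    for rec in protocol.for_child(series.child_id):
        inside = (starts >= rec.start) & (ends <= rec.stop)
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            warnings.warn(
                f"protocol interval {rec.behaviour.value} "
                f"[{rec.start} .. {rec.stop}) for child {rec.child_id} matched "
                f"no full epoch of the {series.device.value}/{series.position.value} series",
                stacklevel=2,
            )
            continue
        rows.append(
            pd.DataFrame(
                {
                    "child_id": series.child_id,
                    "device": series.device,
                    "position": series.position,
                    "behaviour": rec.behaviour,
                    "epoch_index": np.arange(idx.size),
                    "count": series.counts[idx],
                }
            )
        )
    if not rows:
        return empty_labeled()
    return pd.concat(rows, ignore_index=True)


def extract_all_segments(
    series: Iterable[EpochSeries], protocol: BehaviourProtocol
) -> pd.DataFrame:
    """Pool labelled epochs across every series (concatenation across children)."""
    frames = [extract_segments(s, protocol) for s in series]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return empty_labeled()
    return pd.concat(frames, ignore_index=True)


def validate_durations(labeled: pd.DataFrame, epoch_seconds: float = 30.0) -> pd.DataFrame:
    """Check that each (child, behaviour) bout lasts between 8 and 10 minutes.

    The calibration protocol repeats an activity until at least 8 minutes
    are accumulated and stops it at about 10; a bout outside [8, 10] min is
    flagged.  Durations are counted per channel and reported for the
    longest channel of each cell (channels are generated in lockstep, so
    they normally agree).
    """
    if labeled.empty:
        raise ValidationError("labelled counts are empty")
    per_cell = (
        labeled.groupby(["child_id", "behaviour", "device", "position"], sort=True, observed=True)
        .size()
        .groupby(["child_id", "behaviour"], observed=True)
        .max()
    )
    minutes = per_cell * float(epoch_seconds) / 60.0
    report = minutes.rename("minutes").reset_index()
    report["within_limits"] = (report["minutes"] >= 8.0) & (report["minutes"] <= 10.0)
    return report
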