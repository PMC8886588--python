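"""Epoch-based actigraphy/light recordings, sleep diaries and acrophase records.

All on-disk formats are plain comma-delimited UTF-8 CSV with ISO-8601 times:

* recording:  ``timestamp,activity,lux``
* diary:      ``date,onset_time,offset_time``
* acrophase:  ``window_start,window_end,acrophase_time``

Times are naive local times; the synthetic calendar is DST-free.  Epoch
intervals are half-open ``[t, t + epoch_length)`` and an episode covers the
epochs whose left edge falls inside it.  Gaps in a recording are represented
by masked epochs, never by omitted rows, so the in-memory series is always
gap-free and uniformly sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError, InsufficientDataError

SECONDS_PER_DAY = 86_400


@dataclass
class EpochSeries:
    """Uniformly sampled activity counts and illuminance at a fixed epoch length.

    Parameters
    ----------
    start_time
        Left edge of the first epoch (naive local time).
    epoch_length
        Epoch duration in seconds; must divide 24 h exactly.
    activity, lux
        Per-epoch non-negative values, equal length.
    missing
        Boolean mask; ``True`` marks epochs with no observation.  Masked
        epochs are excluded from all metric computations (zero lux is
        meaningful darkness, not missingness).
    """

    start_time: datetime
    epoch_length: int
    activity: np.ndarray
    lux: np.ndarray
    missing: np.ndarray = None

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        self.lux = np.asarray(self.lux, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.activity.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (len(self.activity) == len(self.lux) == len(self.missing)):
            raise DataError("activity, lux and missing must have equal length")
        if SECONDS_PER_DAY % int(self.epoch_length) != 0:
            raise DataError(
                f"epoch_length {self.epoch_length} s must divide 24 h exactly"
            )
        ok = ~self.missing
        if np.any(self.activity[ok] < 0) or np.any(self.lux[ok] < 0):
            raise DataError("non-missing activity/lux values must be >= 0")

    # -- derived geometry ---------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return len(self.activity)

    @property
    def epoch_hours(self) -> float:
        return self.epoch_length / 3600.0

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // int(self.epoch_length)

    @property
    def span_hours(self) -> float:
        return self.n_epochs * self.epoch_hours

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.n_epochs * self.epoch_length)

    def times(self) -> pd.DatetimeIndex:
        """Left edge of every epoch."""
        return pd.date_range(
            self.start_time, periods=self.n_epochs, freq=f"{int(self.epoch_length)}s"
        )

    def hours_since_start(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_hours

    def clock_hours(self) -> np.ndarray:
        """Clock time (h, mod 24) of every epoch's left edge."""
        t0 = (
            self.start_time.hour
            + self.start_time.minute / 60.0
            + self.start_time.second / 3600.0
        )
        return (t0 + self.hours_since_start()) % 24.0

    def day_index(self) -> np.ndarray:
        """Calendar-day index (0-based, day of ``start_time`` = 0) per epoch."""
        midnight = datetime(
            self.start_time.year, self.start_time.month, self.start_time.day
        )
        off = (self.start_time - midnight).total_seconds()
        secs = off + np.arange(self.n_epochs) * float(self.epoch_length)
        return (secs // SECONDS_PER_DAY).astype(int)


@dataclass(frozen=True)
class SleepEpisode:
    """One sleep onset→offset interval on the real-time axis."""

    onset: datetime
    offset: datetime
    source: str = "diary"  # "diary" or "model"

    def __post_init__(self):
        if self.source not in ("diary", "model"):
            raise DataError(f"unknown episode source {self.source!r}")
        if self.offset <= self.onset:
            raise DataError("episode offset must follow onset")
        if self.duration_hours >= 24.0:
            raise DataError("episode duration must be < 24 h")

    @property
    def duration_hours(self) -> float:
        return (self.offset - self.onset).total_seconds() / 3600.0

    @property
    def midpoint(self) -> datetime:
        return self.onset + (self.offset - self.onset) / 2

    @staticmethod
    def clock_hour(t: datetime) -> float:
        return t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9


@dataclass(frozen=True)
class AcrophaseRecord:
    """Timing of one urinary aMT6s acrophase and its collection window."""

    acrophase_time: datetime
    window_start: datetime
    window_end: datetime

    def __post_init__(self):
        if not (self.window_start <= self.acrophase_time <= self.window_end):
            raise DataError("acrophase_time must lie within the collection window")


@dataclass
class ParticipantRecord:
    """One participant's recording, diary episodes and acrophase records."""

    id: str
    group: str  # "case" or "control"
    recording: EpochSeries
    episodes: list = field(default_factory=list)
    acrophases: list = field(default_factory=list)

    def __post_init__(self):
        if self.group not in ("case", "control"):
            raise DataError(f"unknown group {self.group!r}")
        eps = sorted(self.episodes, key=lambda e: e.onset)
        for a, b in zip(eps, eps[1:]):
            if b.onset < a.offset:
                raise DataError(f"overlapping episodes at {b.onset}")
        self.episodes = eps
        t0, t1 = self.recording.start_time, self.recording.end_time
        for e in eps:
            if e.onset < t0 or e.offset > t1:
                raise DataError(f"episode {e.onset} outside recording span")
        for a in self.acrophases:
            if a.acrophase_time < t0 or a.acrophase_time > t1:
                raise DataError("acrophase outside recording span")


# ---------------------------------------------------------------------------
# recording CSV
# ---------------------------------------------------------------------------

def read_recording(path, epoch_length: int = 120) -> EpochSeries:
    """Read a ``timestamp,activity,lux`` CSV into a gap-free :class:`EpochSeries`.

    Rows missing from the file become masked epochs.  Rows whose timestamps do
    not fall on the declared grid are re-binned by left-edge alignment (all
    rows landing in one epoch are averaged).
    """
    df = pd.read_csv(path)
    for col in ("timestamp", "activity", "lux"):
        if col not in df.columns:
            raise FormatError(f"recording CSV missing column {col!r}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamp in {path}: {exc}") from None
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise DataError(f"duplicate timestamp {dup} in {path}")
    if not ts.is_monotonic_increasing:
        order = np.argsort(ts.to_numpy())
        df = df.iloc[order].reset_index(drop=True)
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    span_s = (ts.iloc[-1] - ts.iloc[0]).total_seconds() + epoch_length
    if span_s < SECONDS_PER_DAY:
        raise InsufficientDataError(f"recording spans {span_s / 3600:.1f} h < 24 h")

    t0 = ts.iloc[0].to_pydatetime()
    idx = ((ts - ts.iloc[0]).dt.total_seconds() // epoch_length).astype(int).to_numpy()
    n = int(idx[-1]) + 1
    act = np.zeros(n)
    lux = np.zeros(n)
    cnt = np.zeros(n)
    np.add.at(act, idx, df["activity"].to_numpy(dtype=float))
    np.add.at(lux, idx, df["lux"].to_numpy(dtype=float))
    np.add.at(cnt, idx, 1.0)
    missing = cnt == 0
    cnt[missing] = 1.0
    return EpochSeries(t0, epoch_length, act / cnt, lux / cnt, missing)


def write_recording(series: EpochSeries, path) -> None:
    """Write non-missing epochs as ``timestamp,activity,lux`` rows (gaps are
    represented by absent rows and restored as masked epochs on re-read)."""
    keep = ~series.missing
    pd.DataFrame(
        {
            "timestamp": series.times()[keep].strftime("%Y-%m-%dT%H:%M:%S"),
            "activity": series.activity[keep],
            "lux": series.lux[keep],
        }
    ).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# diary CSV
# ---------------------------------------------------------------------------

def read_diary(path) -> list:
    """Read a ``date,onset_time,offset_time`` CSV into sorted episodes.

    ``offset_time`` <= ``onset_time`` rolls the offset to the next calendar
    day (an episode spanning midnight is written on the row of its onset day).
    """
    df = pd.read_csv(path)
    for col in ("date", "onset_time", "offset_time"):
        if col not in df.columns:
            raise FormatError(f"diary CSV missing column {col!r}")
    episodes = []
    for _, row in df.iterrows():
        try:
            day = pd.Timestamp(row["date"])
            on = pd.Timestamp(f"{row['date']} {row['onset_time']}")
            off = pd.Timestamp(f"{row['date']} {row['offset_time']}")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"unparseable diary row {row.to_dict()}: {exc}") from None
        if off <= on:
            off += pd.Timedelta(days=1)
        episodes.append(
            SleepEpisode(on.to_pydatetime(), off.to_pydatetime(), source="diary")
        )
    episodes.sort(key=lambda e: e.onset)
    for a, b in zip(episodes, episodes[1:]):
        if b.onset < a.offset:
            raise DataError(f"overlapping diary episodes at {b.onset}")
    return episodes


def write_diary(episodes: Iterable[SleepEpisode], path) -> None:
    rows = [
        {
            "date": e.onset.strftime("%Y-%m-%d"),
            "onset_time": e.onset.strftime("%H:%M:%S"),
            "offset_time": e.offset.strftime("%H:%M:%S"),
        }
        for e in sorted(episodes, key=lambda e: e.onset)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# acrophase CSV
# ---------------------------------------------------------------------------

def read_acrophases(path) -> list:
    df = pd.read_csv(path)
    for col in ("window_start", "window_end", "acrophase_time"):
        if col not in df.columns:
            raise FormatError(f"acrophase CSV missing column {col!r}")
    try:
        ws = pd.to_datetime(df["window_start"], format="ISO8601")
        we = pd.to_datetime(df["window_end"], format="ISO8601")
        at = pd.to_datetime(df["acrophase_time"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable acrophase time: {exc}") from None
    return [
        AcrophaseRecord(t.to_pydatetime(), s.to_pydatetime(), e.to_pydatetime())
        for s, e, t in zip(ws, we, at)
    ]


def write_acrophases(records: Iterable[AcrophaseRecord], path) -> None:
    fmt = "%Y-%m-%dT%H:%M:%S"
    rows = [
        {
            "window_start": r.window_start.strftime(fmt),
            "window_end": r.window_end.strftime(fmt),
            "acrophase_time": r.acrophase_time.strftime(fmt),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
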