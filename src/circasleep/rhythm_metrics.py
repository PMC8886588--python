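"""Non-parametric rhythm analysis: period estimation by data folding,
circular statistics of sleep timing, and daily light-exposure summaries.

The period estimator makes no assumption about waveform shape: the signal is
folded at each candidate period into phase bins one epoch wide, and the
candidate minimizing the residual variance (pooled within-bin variance as a
fraction of total variance) is the dominant period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, time as dtime
from typing import Iterable, Sequence

import numpy as np

from .data_io import EpochSeries, SleepEpisode
from .exceptions import (
    DegenerateSignalError,
    InsufficientDataError,
    PeriodRangeError,
)

HOURS_PER_DAY = 24.0


# ---------------------------------------------------------------------------
# folding period scan
# ---------------------------------------------------------------------------

@dataclass
class PeriodScan:
    """Residual-variance profile over candidate periods.

    ``depth`` is a flatness diagnostic (min residual variance / median); a
    value near 1 means the scan found no structure (e.g. white noise).
    ``sparse_bin_fraction`` flags candidates where phase bins held < 2
    samples (those bins contribute zero within-bin variance).
    """

    candidate_periods: np.ndarray  # h
    residual_variance: np.ndarray  # in [0, 1]
    dominant_period: float         # h
    depth: float
    sparse_bin_fraction: np.ndarray

    @property
    def min_residual(self) -> float:
        return float(self.residual_variance.min())


def fold_period_scan(
    series: EpochSeries,
    channel: str = "activity",
    period_range: tuple = (20.0, 28.0),
) -> PeriodScan:
    """Scan candidate periods by folding ``series.<channel>`` modulo each
    candidate, in steps of one epoch (the data resolution).

    For each candidate period P, non-missing epochs are binned by phase
    (bin width = epoch length); the residual variance is the pooled
    within-bin sum of squares divided by the total sum of squares.  The
    dominant period is the candidate with the smallest residual variance
    (ties break to the smallest period).
    """
    values = np.asarray(getattr(series, channel), dtype=float)
    valid = ~series.missing
    step_h = series.epoch_hours
    span_h = series.span_hours
    lo, hi = float(period_range[0]), float(period_range[1])
    if lo <= 2 * step_h or hi > span_h / 3.0:
        raise PeriodRangeError(
            f"period range ({lo}, {hi}) h must lie within "
            f"({2 * step_h:.3f}, {span_h / 3.0:.3f}) h"
        )
    v = values[valid]
    t = np.nonzero(valid)[0].astype(float) * step_h  # left-edge epoch times
    total_ss = float(np.sum((v - v.mean()) ** 2))
    if total_ss == 0.0:
        raise DegenerateSignalError("constant signal: period is undefined")

    n_cand = int(round((hi - lo) / step_h)) + 1
    periods = lo + step_h * np.arange(n_cand)
    resid = np.empty(n_cand)
    sparse = np.empty(n_cand)
    v2 = v * v
    for i, P in enumerate(periods):
        nb = int(math.ceil(P / step_h))
        bins = np.floor(np.mod(t, P) / step_h).astype(np.int64)
        bins[bins >= nb] = nb - 1  # guard float round-off at the wrap
        cnt = np.bincount(bins, minlength=nb)
        s = np.bincount(bins, weights=v, minlength=nb)
        s2 = np.bincount(bins, weights=v2, minlength=nb)
        occ = cnt > 0
        within = float(np.sum(s2[occ] - s[occ] ** 2 / cnt[occ]))
        resid[i] = within / total_ss
        sparse[i] = np.mean(cnt < 2)
    best = int(np.argmin(resid))  # argmin takes the first (smallest) period on ties
    depth = float(resid.min() / np.median(resid)) if np.median(resid) > 0 else 1.0
    return PeriodScan(periods, resid, float(periods[best]), depth, sparse)


# ---------------------------------------------------------------------------
# circular statistics of clock times
# ---------------------------------------------------------------------------

@dataclass
class CircularTimeStats:
    mean_time: float          # clock h in [0, 24); nan when undefined
    resultant_length: float   # in [0, 1]
    circular_variance: float  # 1 - resultant_length
    circular_sd: float        # h; inf when resultant_length == 0
    n: int
    mean_undefined: bool = False


def _to_hours(t) -> float:
    if isinstance(t, datetime):
        return SleepEpisode.clock_hour(t)
    if isinstance(t, dtime):
        return t.hour + t.minute / 60.0 + t.second / 3600.0
    return float(t) % HOURS_PER_DAY


def circular_time_stats(times: Iterable) -> CircularTimeStats:
    """Circular mean/variance of clock times (datetimes, times, or hours).

    Times map to angles by t -> 2*pi*t/24; the mean direction and resultant
    length come from the vector average.  A zero resultant length leaves the
    mean undefined: the result is flagged, not raised.
    """
    hours = np.array([_to_hours(t) for t in times], dtype=float)
    if len(hours) < 2:
        raise InsufficientDataError("need >= 2 times for circular statistics")
    ang = hours * 2 * np.pi / HOURS_PER_DAY
    z = np.exp(1j * ang).mean()
    R = float(np.abs(z))
    if R < 1e-12:
        return CircularTimeStats(float("nan"), 0.0, 1.0, float("inf"),
                                 len(hours), mean_undefined=True)
    mean_h = float((np.angle(z) * HOURS_PER_DAY / (2 * np.pi)) % HOURS_PER_DAY)
    if mean_h >= HOURS_PER_DAY:  # float round-off at the wrap
        mean_h = 0.0
    R = min(R, 1.0)
    sd_h = (HOURS_PER_DAY / (2 * np.pi)) * math.sqrt(max(0.0, -2.0 * math.log(R)))
    return CircularTimeStats(mean_h, R, 1.0 - R, sd_h, len(hours))


def circular_distance_hours(a: float, b: float) -> float:
    """Shortest distance between two clock times on the 24-h circle."""
    d = (a - b) % HOURS_PER_DAY
    return min(d, HOURS_PER_DAY - d)


# ---------------------------------------------------------------------------
# sleep timing summary
# ---------------------------------------------------------------------------

@dataclass
class SleepTimingSummary:
    n_episodes: int
    duration_mean: float  # h, linear
    duration_sd: float    # h, linear
    onset: CircularTimeStats
    offset: CircularTimeStats
    mid_sleep: CircularTimeStats


def sleep_timing_summary(episodes: Sequence[SleepEpisode]) -> SleepTimingSummary:
    """Linear mean/SD of duration and circular statistics of onset, offset
    and mid-sleep (onset + duration/2) clock times.  Seven or more episodes
    are recommended for stable circular estimates; fewer than two is an
    error."""
    if len(episodes) < 2:
        raise InsufficientDataError(
            f"need >= 2 episodes for a timing summary, got {len(episodes)}"
        )
    durations = np.array([e.duration_hours for e in episodes])
    return SleepTimingSummary(
        n_episodes=len(episodes),
        duration_mean=float(durations.mean()),
        duration_sd=float(durations.std(ddof=1)),
        onset=circular_time_stats([e.onset for e in episodes]),
        offset=circular_time_stats([e.offset for e in episodes]),
        mid_sleep=circular_time_stats([e.midpoint for e in episodes]),
    )


# ---------------------------------------------------------------------------
# light exposure metrics
# ---------------------------------------------------------------------------

@dataclass
class LightMetrics:
    median_bright_hours: float   # h/day with lux strictly > threshold
    median_daily_lux: float      # median over days of within-day mean lux
    median_daily_log_lux: float  # same for log(lux + 1)
    n_days: int
    bright_threshold: float = 500.0


def light_metrics(series: EpochSeries, bright_lux: float = 500.0) -> LightMetrics:
    """Per-day bright-light hours (lux strictly > ``bright_lux``), mean lux
    and mean log(lux+1), each summarized as the median across calendar days.
    Missing epochs are excluded; days with no valid epoch are skipped."""
    day = series.day_index()
    valid = ~series.missing
    lux = series.lux
    eph = series.epoch_hours
    bright, mean_lux, mean_log = [], [], []
    for d in np.unique(day):
        sel = (day == d) & valid
        if not np.any(sel):
            continue
        lv = lux[sel]
        bright.append(np.count_nonzero(lv > bright_lux) * eph)
        mean_lux.append(lv.mean())
        mean_log.append(np.log(lv + 1.0).mean())
    if not bright:
        raise InsufficientDataError("all days fully masked")
    if len(bright) < 7:
        raise InsufficientDataError(
            f"need >= 7 days with data for light metrics, got {len(bright)}"
        )
    return LightMetrics(
        float(np.median(bright)),
        float(np.median(mean_lux)),
        float(np.median(mean_log)),
        len(bright),
        bright_lux,
    )
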