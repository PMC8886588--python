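"""Available-light profiles, entrainment classification and intervention design.

An *available-light profile* is the 24-h environmental illuminance a person
could receive if awake; the model samples it only during model-predicted
wake, so interventions change the environment, never force a wake time.  The
design surface is a grid over (daytime peak lux, evening lux): each point is
classified as producing an entrained (24-h) or drifting (non-24-h) sleep
rhythm, and among entrained points the mean sleep offset is the outcome used
to target a desired wake time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import SleepEpisode
from .exceptions import InsufficientDataError

DEFAULT_RISE, DEFAULT_PEAK, DEFAULT_DECLINE = 7.0, 13.0, 21.0


@dataclass(frozen=True)
class AvailableLightProfile:
    """24-h periodic light availability: a raised-cosine day bump peaking at
    ``peak_time`` on a constant evening/night floor ``L_eve``.

    The profile climbs smoothly from the floor at ``rise_time`` to ``L_day``
    at ``peak_time`` and returns to the floor by ``decline_time``; the cosine
    half-waves make it continuously differentiable and 24-h periodic.
    """

    L_day: float
    L_eve: float
    rise_time: float = DEFAULT_RISE
    peak_time: float = DEFAULT_PEAK
    decline_time: float = DEFAULT_DECLINE

    def __post_init__(self):
        if self.L_eve < 0 or self.L_day < self.L_eve:
            raise ValueError("require L_day >= L_eve >= 0")
        if not (self.rise_time < self.peak_time < self.decline_time <= 24.0):
            raise ValueError("require rise_time < peak_time < decline_time <= 24")

    def value(self, clock_h):
        """Illuminance (lux) at clock time(s) ``clock_h`` (hours, mod 24)."""
        t = np.asarray(clock_h, dtype=float) % 24.0
        bump = np.zeros_like(t)
        up = (t >= self.rise_time) & (t < self.peak_time)
        down = (t >= self.peak_time) & (t < self.decline_time)
        bump[up] = 0.5 * (
            1 - np.cos(np.pi * (t[up] - self.rise_time) / (self.peak_time - self.rise_time))
        )
        bump[down] = 0.5 * (
            1 + np.cos(np.pi * (t[down] - self.peak_time) / (self.decline_time - self.peak_time))
        )
        out = self.L_eve + (self.L_day - self.L_eve) * bump
        return out if out.shape else float(out)

    def sample(self, n_epochs: int, epoch_length: int = 120, start_clock: float = 0.0):
        clock = (start_clock + np.arange(n_epochs) * epoch_length / 3600.0) % 24.0
        return self.value(clock)


def make_profile(L_day: float, L_eve: float, shape: dict = None) -> AvailableLightProfile:
    """Build a profile from its two intensity levers; ``shape`` may override
    the rise/peak/decline clock times."""
    shape = shape or {}
    return AvailableLightProfile(L_day=L_day, L_eve=L_eve, **shape)


# ---------------------------------------------------------------------------
# entrainment classification
# ---------------------------------------------------------------------------

@dataclass
class EntrainmentResult:
    entrained: bool
    onset_period: float
    mean_offset: float  # clock h; nan unless entrained
    failed: bool = False


def _circular_mean_hours(hours) -> float:
    ang = np.asarray(hours) * 2 * np.pi / 24.0
    m = np.angle(np.exp(1j * ang).mean())
    h = float((m * 24.0 / (2 * np.pi)) % 24.0)
    return 0.0 if h >= 24.0 else h


def classify_entrainment(
    params,
    profile: AvailableLightProfile,
    days: float = 42.0,
    tol_minutes: float = 2.0,
    transient_days: float = 14.0,
    window_days: float = 28.0,
) -> EntrainmentResult:
    """Simulate self-selected exposure to ``profile`` and classify the sleep
    rhythm.  Entrained iff the onset period over the final ``window_days``
    post-transient days is within ``tol_minutes`` of 24 h; the mean sleep
    offset (circular, clock h) is reported only for entrained points."""
    from .model import onset_period, simulate  # local: avoid cycle

    if days < transient_days + window_days:
        raise ValueError("days must cover the transient plus the analysis window")
    try:
        sim = simulate(params, profile, days=days, mode="self_selected")
        eps = sim.episodes_after(24.0 * (days - window_days))
        period = onset_period(eps)
    except InsufficientDataError:
        # pathological light/physiology: no scorable rhythm
        return EntrainmentResult(False, float("nan"), float("nan"), failed=True)
    except Exception:
        return EntrainmentResult(False, float("nan"), float("nan"), failed=True)
    entrained = abs(period - 24.0) <= tol_minutes / 60.0
    if entrained:
        offs = [SleepEpisode.clock_hour(e.offset) for e in eps]
        mean_off = _circular_mean_hours(offs)
    else:
        mean_off = float("nan")
    return EntrainmentResult(entrained, period, mean_off)


@dataclass
class EntrainmentMap:
    """Grid over (L_day, L_eve) with entrainment class, onset period and
    mean sleep offset at every point."""

    L_day_grid: np.ndarray
    L_eve_grid: np.ndarray
    entrained: np.ndarray      # (n_day, n_eve) bool
    onset_period: np.ndarray   # h
    mean_offset: np.ndarray    # clock h, nan when not entrained
    failed: np.ndarray         # bool

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, ld in enumerate(self.L_day_grid):
            for j, le in enumerate(self.L_eve_grid):
                rows.append(
                    dict(
                        L_day=ld,
                        L_eve=le,
                        entrained=bool(self.entrained[i, j]),
                        onset_period=self.onset_period[i, j],
                        mean_offset=self.mean_offset[i, j],
                        failed=bool(self.failed[i, j]),
                    )
                )
        return pd.DataFrame(rows)


def entrainment_map(
    params,
    L_day_grid: Sequence[float] = None,
    L_eve_grid: Sequence[float] = None,
    shape: dict = None,
    **classify_kw,
) -> EntrainmentMap:
    """Classify entrainment at every (L_day, L_eve) grid point.

    Default grid: 67 x 67 log-spaced points, L_day in [10, 2000] lux and
    L_eve in [0.5, 100] lux.  Individual simulation failures are recorded in
    ``failed`` and the map is still returned.
    """
    if L_day_grid is None:
        L_day_grid = np.geomspace(10.0, 2000.0, 67)
    if L_eve_grid is None:
        L_eve_grid = np.geomspace(0.5, 100.0, 67)
    L_day_grid = np.asarray(L_day_grid, dtype=float)
    L_eve_grid = np.asarray(L_eve_grid, dtype=float)
    if np.any(np.diff(L_day_grid) <= 0) or np.any(np.diff(L_eve_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    nd, ne = len(L_day_grid), len(L_eve_grid)
    ent = np.zeros((nd, ne), dtype=bool)
    per = np.full((nd, ne), np.nan)
    off = np.full((nd, ne), np.nan)
    fail = np.zeros((nd, ne), dtype=bool)
    for i, ld in enumerate(L_day_grid):
        for j, le in enumerate(L_eve_grid):
            if ld < le:  # infeasible corner of the grid
                fail[i, j] = True
                continue
            res = classify_entrainment(params, make_profile(ld, le, shape), **classify_kw)
            ent[i, j] = res.entrained
            per[i, j] = res.onset_period
            off[i, j] = res.mean_offset
            fail[i, j] = res.failed
    return EntrainmentMap(L_day_grid, L_eve_grid, ent, per, off, fail)


# ---------------------------------------------------------------------------
# intervention search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    L_day: float
    L_eve: float
    mean_offset: float
    onset_period: float
    light_change: float  # |dL_day| + |dL_eve| from the reference profile


@dataclass
class DesignResult:
    candidates: list
    feasible: bool
    target_offset: float
    tol_hours: float


def _circ_dist_hours(a, b) -> float:
    d = (a - b) % 24.0
    return min(d, 24.0 - d)


def design_intervention(
    params,
    target_offset: float,
    offsets_tol: float = 0.25,
    emap: EntrainmentMap = None,
    reference: tuple = (160.0, 30.0),
    **map_kw,
) -> DesignResult:
    """All entrained grid points whose mean sleep offset is within
    ``offsets_tol`` hours of ``target_offset`` (clock h), sorted by total
    light change from the reference (L_day, L_eve).  An empty candidate list
    marks the target infeasible for this physiology."""
    if emap is None:
        emap = entrainment_map(params, **map_kw)
    cands = []
    for i, ld in enumerate(emap.L_day_grid):
        for j, le in enumerate(emap.L_eve_grid):
            if not emap.entrained[i, j]:
                continue
            if _circ_dist_hours(emap.mean_offset[i, j], target_offset) <= offsets_tol:
                cands.append(
                    Candidate(
                        float(ld),
                        float(le),
                        float(emap.mean_offset[i, j]),
                        float(emap.onset_period[i, j]),
                        abs(ld - reference[0]) + abs(le - reference[1]),
                    )
                )
    cands.sort(key=lambda c: c.light_change)
    return DesignResult(cands, bool(cands), target_offset, offsets_tol)
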