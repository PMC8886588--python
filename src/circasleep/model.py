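"""Coupled sleep-wake / circadian-pacemaker model and its simulation.

The model couples three well-established physiological components:

* a mutually inhibitory sleep/wake flip-flop: mean voltages ``V_v`` (sleep-
  active, ventrolateral preoptic) and ``V_m`` (wake-active, monoaminergic)
  with sigmoidal firing rates and cross-inhibition;
* a homeostatic sleep pressure ``H`` that charges during wake (driven by the
  wake-population firing rate) and discharges during sleep; and
* a light-entrained limit-cycle (van der Pol-type) circadian pacemaker
  ``(x, x_c)`` with a phototransduction pool ``n`` converting retinal
  illuminance into circadian drive.

Two parameters are individual-specific and fitted from data: the intrinsic
circadian period ``tau_c`` and ``delta_D``, the deviation of the mean drive
for wakefulness from its default (larger ``delta_D`` -> more wake, shorter
sleep).  Everything else is fixed at literature values for this model family
and verified against structural invariants (free-running pacemaker period
equals ``tau_c``; ~8 h consolidated sleep per day at ``delta_D = 0`` under a
regular bright light routine).

Light enters only during model wake (eyes closed during sleep): in
``self_selected`` mode an availability profile is sampled at clock time while
awake; in ``imposed`` mode an observed lux series is used, still masked to
zero during model sleep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from . import _engine
from .data_io import SleepEpisode
from .exceptions import InsufficientDataError, NumericalError

DEFAULT_START = datetime(2024, 1, 1)
DEFAULT_EPOCH_S = 120
TRANSIENT_DAYS = 14


@dataclass(frozen=True)
class ModelParams:
    """Model parameters.  ``tau_c`` and ``delta_D`` are the two fitted,
    individual-specific parameters; the rest are fixed physiology.

    Units: voltages mV, firing rates s^-1, ``tau_v``/``tau_m`` s,
    ``chi``/``tau_c`` h, ``alpha_0``/``beta`` min^-1, ``I_0`` lux.
    """

    tau_c: float = 24.2
    delta_D: float = 0.0
    # sleep-wake flip-flop + homeostat
    Q_max: float = 100.0
    theta: float = 10.0
    sigma: float = 3.0
    tau_v: float = 10.0
    tau_m: float = 10.0
    nu_vm: float = -2.1
    nu_mv: float = -1.8
    nu_vh: float = 1.0
    nu_vc: float = -3.37
    A_v: float = -10.2
    A_m: float = 1.3
    chi: float = 45.0
    mu: float = 4.4
    # phototransduction and pacemaker light coupling
    alpha_0: float = 0.05
    beta: float = 0.0075
    I_0: float = 9500.0
    p: float = 0.5
    G: float = 33.75
    k: float = 0.55
    b: float = 0.4
    q: float = 1.0 / 3.0
    mu_p: float = 0.13
    f: float = 0.99669
    # circadian drive read-out C = (1 + cx*x + cxc*x_c)/2
    cx: float = 0.8
    cxc: float = -0.47

    def __post_init__(self):
        if not (22.0 <= self.tau_c <= 28.0):
            raise ValueError(f"tau_c {self.tau_c} outside physiological [22, 28] h")
        for name in ("Q_max", "sigma", "tau_v", "tau_m", "chi", "alpha_0", "beta",
                     "I_0", "mu_p", "f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_array(self) -> np.ndarray:
        pp = np.empty(_engine.N_PARAMS)
        pp[_engine.I_TAU_C] = self.tau_c
        pp[_engine.I_DELTA_D] = self.delta_D
        pp[_engine.I_QMAX] = self.Q_max
        pp[_engine.I_THETA] = self.theta
        pp[_engine.I_SIGMA] = self.sigma
        pp[_engine.I_TAU_V] = self.tau_v
        pp[_engine.I_TAU_M] = self.tau_m
        pp[_engine.I_NU_VM] = self.nu_vm
        pp[_engine.I_NU_MV] = self.nu_mv
        pp[_engine.I_NU_VH] = self.nu_vh
        pp[_engine.I_NU_VC] = self.nu_vc
        pp[_engine.I_A_V] = self.A_v
        pp[_engine.I_A_M] = self.A_m
        pp[_engine.I_CHI] = self.chi
        pp[_engine.I_MU] = self.mu
        pp[_engine.I_ALPHA0] = self.alpha_0
        pp[_engine.I_BETA] = self.beta
        pp[_engine.I_I0] = self.I_0
        pp[_engine.I_P] = self.p
        pp[_engine.I_G] = self.G
        pp[_engine.I_K] = self.k
        pp[_engine.I_B] = self.b
        pp[_engine.I_Q] = self.q
        pp[_engine.I_MU_P] = self.mu_p
        pp[_engine.I_F] = self.f
        pp[_engine.I_CX] = self.cx
        pp[_engine.I_CXC] = self.cxc
        return pp

    def evolve(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass
class ModelState:
    """State vector: flip-flop voltages, homeostatic pressure, pacemaker
    pair and activated photoreceptor fraction."""

    V_v: float
    V_m: float
    H: float
    x: float
    x_c: float
    n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V_v, self.V_m, self.H, self.x, self.x_c, self.n])

    @classmethod
    def from_array(cls, y) -> "ModelState":
        return cls(*[float(v) for v in y])

    @property
    def awake(self) -> bool:
        return self.V_m > self.V_v


def circadian_drive(x, x_c, params: ModelParams = None):
    """Circadian wake-propensity drive C(x, x_c); its per-cycle minimum falls
    in the late biological night (the CWPM, the model's phase marker)."""
    cx = params.cx if params is not None else 0.8
    cxc = params.cxc if params is not None else -0.47
    return 0.5 * (1.0 + cx * x + cxc * x_c)


def derivatives(state, t, params: ModelParams, I: float):
    """Right-hand side of the six-dimensional system, in h^-1.

    Pure-Python reference implementation; accepts complex-valued state for
    complex-step differentiation.  ``state`` may be a :class:`ModelState` or
    a length-6 array ``(V_v, V_m, H, x, x_c, n)``; ``I`` is the illuminance
    (lux) reaching the retina at time ``t``.
    """
    if I < 0:
        raise ValueError("illuminance must be >= 0")
    y = state.as_array() if isinstance(state, ModelState) else np.asarray(state)
    V_v, V_m, H, x, x_c, n = y
    p = params
    Q_v = p.Q_max / (1.0 + np.exp((p.theta - V_v) / p.sigma))
    Q_m = p.Q_max / (1.0 + np.exp((p.theta - V_m) / p.sigma))
    C = 0.5 * (1.0 + p.cx * x + p.cxc * x_c)
    D_v = p.nu_vh * H + p.nu_vc * C + p.A_v - p.delta_D
    dV_v = (-V_v + p.nu_vm * Q_m + D_v) / (p.tau_v / 3600.0)
    dV_m = (-V_m + p.nu_mv * Q_v + p.A_m) / (p.tau_m / 3600.0)
    dH = (-H + p.mu * Q_m) / p.chi
    alpha = p.alpha_0 * (I / p.I_0) ** p.p if I > 0 else 0.0
    dn = 60.0 * (alpha * (1.0 - n) - p.beta * n)
    Bhat = p.G * alpha * (1.0 - n)
    B = Bhat * (1.0 - p.b * x) * (1.0 - p.b * x_c)
    omega2 = (24.0 / (p.f * p.tau_c)) ** 2
    pi12 = math.pi / 12.0
    dx = pi12 * (x_c + p.mu_p * (x / 3.0 + 4.0 * x**3 / 3.0 - 256.0 * x**7 / 105.0) + B)
    dx_c = pi12 * (p.q * B * x_c - x * (omega2 + p.k * B))
    out = np.array([dV_v, dV_m, dH, dx, dx_c, dn])
    if not np.iscomplexobj(out) and not np.all(np.isfinite(out)):
        raise NumericalError(f"non-finite derivative at t={t}: state={y}")
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Trajectory, per-epoch wake indicator, model sleep episodes and
    circadian phase markers from one simulation."""

    params: ModelParams
    start_time: datetime
    epoch_length: int
    t_hours: np.ndarray          # epoch left edges + final instant
    states: np.ndarray           # (n_epochs + 1, 6)
    wake: np.ndarray             # bool, same length
    episodes: list               # SleepEpisode(source="model")
    transition_times: np.ndarray
    transition_dirs: np.ndarray
    ok: bool = True
    warn_short: bool = False     # span too short for an entrainment summary
    dropped_episodes: int = 0

    @property
    def start_clock(self) -> float:
        return SleepEpisode.clock_hour(self.start_time)

    def clock_hours(self) -> np.ndarray:
        return (self.start_clock + self.t_hours) % 24.0

    def to_datetime(self, hours) -> list:
        return [self.start_time + timedelta(hours=float(h)) for h in np.atleast_1d(hours)]

    def circadian_drive_series(self) -> np.ndarray:
        return circadian_drive(self.states[:, 3], self.states[:, 4], self.params)

    def cwpm_hours(self) -> np.ndarray:
        return cwpm_times(self)

    def cwpm_datetimes(self) -> list:
        return self.to_datetime(self.cwpm_hours())

    def episodes_after(self, t_hours: float) -> list:
        t = self.start_time + timedelta(hours=t_hours)
        return [e for e in self.episodes if e.onset >= t]

    def onset_period(self, transient_days: int = TRANSIENT_DAYS) -> float:
        return onset_period(self.episodes_after(24.0 * transient_days))


def _as_lux_array(light_source, days, epoch_length, start_clock):
    """Resolve a light source into (available-lux-per-epoch, epoch_length_s)."""
    from .intervention import AvailableLightProfile  # local: avoid cycle

    if isinstance(light_source, AvailableLightProfile):
        if days is None:
            raise ValueError("days must be given with a profile light source")
        n = int(round(days * 86400 / epoch_length))
        clock = (start_clock + np.arange(n) * epoch_length / 3600.0) % 24.0
        return light_source.value(clock), epoch_length
    if isinstance(light_source, np.ndarray):
        lux = np.asarray(light_source, dtype=float)
    else:  # EpochSeries
        lux = np.where(light_source.missing, 0.0, light_source.lux)
        epoch_length = light_source.epoch_length
    if days is not None:
        n = int(round(days * 86400 / epoch_length))
        if n <= len(lux):
            lux = lux[:n]
        else:
            lux = np.concatenate([lux, np.zeros(n - len(lux))])
    return np.ascontiguousarray(lux), epoch_length


def simulate(
    params: ModelParams,
    light_source,
    days: float = None,
    start_time: datetime = None,
    mode: str = "self_selected",
    initial_state=None,
    n_sub: int = 24,
    min_days_for_summary: float = 10.0,
) -> SimResult:
    """Integrate the model under piecewise-constant (per-epoch) light.

    ``light_source`` may be an :class:`~circasleep.intervention.
    AvailableLightProfile` (sampled at clock time), an
    :class:`~circasleep.data_io.EpochSeries` of observed lux, or a raw lux
    array at the default epoch length.  In both modes light is gated to zero
    while the model is asleep; the wake/sleep read-out is ``Q_m > Q_v``
    (equivalently ``V_m > V_v``), the flip-flop's own bistability providing
    hysteresis.
    """
    if mode not in ("imposed", "self_selected"):
        raise ValueError(f"unknown mode {mode!r}")
    if start_time is None:
        start_time = getattr(light_source, "start_time", None) or DEFAULT_START
    start_clock = SleepEpisode.clock_hour(start_time)
    lux, epoch_length = _as_lux_array(light_source, days, DEFAULT_EPOCH_S, start_clock)
    if np.any(lux < 0):
        raise ValueError("illuminance must be >= 0")
    if initial_state is None:
        y0 = initial_state_for_clock(start_clock)
    elif isinstance(initial_state, ModelState):
        y0 = initial_state.as_array()
    else:
        y0 = np.asarray(initial_state, dtype=float)

    epoch_h = epoch_length / 3600.0
    traj, wake, tr_t, tr_d, ok = _engine._integrate(
        y0, lux, epoch_h, n_sub, params.to_array()
    )
    if not ok:
        raise NumericalError("integration produced non-finite state")

    episodes, dropped = _episodes_from_transitions(tr_t, tr_d, start_time)
    span_h = len(lux) * epoch_h
    t_hours = np.arange(len(lux) + 1) * epoch_h
    return SimResult(
        params=params,
        start_time=start_time,
        epoch_length=epoch_length,
        t_hours=t_hours,
        states=traj,
        wake=wake,
        episodes=episodes,
        transition_times=tr_t,
        transition_dirs=tr_d,
        ok=ok,
        warn_short=span_h < min_days_for_summary * 24.0,
        dropped_episodes=dropped,
    )


def _episodes_from_transitions(tr_t, tr_d, start_time):
    episodes = []
    dropped = 0
    onset_h = None
    for t, d in zip(tr_t, tr_d):
        if d == -1:
            onset_h = t
        elif onset_h is not None:
            dur = t - onset_h
            if 0 < dur < 24.0:
                episodes.append(
                    SleepEpisode(
                        start_time + timedelta(hours=float(onset_h)),
                        start_time + timedelta(hours=float(t)),
                        source="model",
                    )
                )
            else:
                dropped += 1
            onset_h = None
    return episodes, dropped


# ---------------------------------------------------------------------------
# phase markers and period read-outs
# ---------------------------------------------------------------------------

def cwpm_times(sim: SimResult, min_separation_h: float = 12.0) -> np.ndarray:
    """Per-cycle circadian wake-propensity minima (hours since sim start).

    The CWPM is the per-cycle minimum of the circadian drive C(x, x_c); each
    minimum is refined by parabolic interpolation of the sampled drive.
    Returns an empty array if the pacemaker is not oscillating.
    """
    C = sim.circadian_drive_series()
    x = sim.states[:, 3]
    if len(C) < 3 or (x.max() - x.min()) < 0.2:
        return np.array([])
    interior = (C[1:-1] < C[:-2]) & (C[1:-1] <= C[2:])
    idx = np.nonzero(interior)[0] + 1
    times = []
    dt = sim.t_hours[1] - sim.t_hours[0]
    for i in idx:
        denom = C[i - 1] - 2 * C[i] + C[i + 1]
        shift = 0.5 * (C[i - 1] - C[i + 1]) / denom if denom > 0 else 0.0
        times.append(sim.t_hours[i] + np.clip(shift, -1, 1) * dt)
    # deduplicate: keep the deeper of any pair closer than min_separation
    out = []
    for t, i in zip(times, idx):
        if out and t - out[-1][0] < min_separation_h:
            if C[i] < out[-1][1]:
                out[-1] = (t, C[i])
        else:
            out.append((t, C[i]))
    return np.array([t for t, _ in out])


def onset_period(episodes: Sequence[SleepEpisode]) -> float:
    """Mean sleep-cycle period (h): slope of the regression of absolute sleep
    onset time on episode index (equivalent to the unwrapped clock-time slope
    plus 24 h)."""
    if len(episodes) < 7:
        raise InsufficientDataError(
            f"need >= 7 episodes for a period estimate, got {len(episodes)}"
        )
    eps = sorted(episodes, key=lambda e: e.onset)
    t0 = eps[0].onset
    hours = np.array([(e.onset - t0).total_seconds() / 3600.0 for e in eps])
    k = np.arange(len(eps))
    slope = np.polyfit(k, hours, 1)[0]
    return float(slope)


def free_running_period(params: ModelParams, days: float = 60.0) -> float:
    """Pacemaker period (h) in constant darkness, from a regression of
    successive minima of x on cycle index."""
    sim = simulate(params, np.zeros(int(days * 86400 / DEFAULT_EPOCH_S)),
                   mode="imposed")
    x = sim.states[:, 3]
    interior = (x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:])
    idx = np.nonzero(interior)[0] + 1
    dt = sim.t_hours[1] - sim.t_hours[0]
    times = []
    for i in idx:
        denom = x[i - 1] - 2 * x[i] + x[i + 1]
        shift = 0.5 * (x[i - 1] - x[i + 1]) / denom if denom > 0 else 0.0
        times.append(sim.t_hours[i] + np.clip(shift, -1, 1) * dt)
    times = np.asarray(times)
    if len(times) < 3:
        raise InsufficientDataError("too few pacemaker cycles to estimate period")
    # drop the first cycles (transient from the entrained initial state)
    times = times[2:]
    return float(np.polyfit(np.arange(len(times)), times, 1)[0])


# ---------------------------------------------------------------------------
# default initial condition: entrained steady state under a regular routine
# ---------------------------------------------------------------------------

_DEFAULT_CYCLE = None


def _standard_routine_lux(n_epochs, epoch_length=DEFAULT_EPOCH_S, start_clock=0.0,
                          L_day=750.0, L_eve=5.0):
    """Regular bright availability used only to compute the default entrained
    state (raised-cosine day bump 07:00-13:00-21:00 on a dim floor)."""
    clock = (start_clock + np.arange(n_epochs) * epoch_length / 3600.0) % 24.0
    up = (clock >= 7.0) & (clock < 13.0)
    down = (clock >= 13.0) & (clock < 21.0)
    bump = np.zeros(n_epochs)
    bump[up] = 0.5 * (1 - np.cos(np.pi * (clock[up] - 7.0) / 6.0))
    bump[down] = 0.5 * (1 + np.cos(np.pi * (clock[down] - 13.0) / 8.0))
    return L_eve + (L_day - L_eve) * bump


def _compute_default_cycle():
    """Spin the default model up to its entrained limit cycle and keep one
    day of states indexed by clock time."""
    params = ModelParams()
    epd = 86400 // DEFAULT_EPOCH_S
    lux = _standard_routine_lux(30 * epd)
    y0 = np.array([3.0, -5.0, 12.0, -1.0, 0.2, 0.01])  # asleep at midnight
    traj, _, _, _, ok = _engine._integrate(
        y0, lux, DEFAULT_EPOCH_S / 3600.0, 24, params.to_array()
    )
    if not ok:  # pragma: no cover
        raise NumericalError("default-state spin-up failed")
    day = traj[29 * epd : 30 * epd]
    clock = (np.arange(epd) * DEFAULT_EPOCH_S / 3600.0) % 24.0
    return clock, day


def initial_state_for_clock(clock_h: float) -> np.ndarray:
    """Entrained default steady state at the given clock time (h)."""
    global _DEFAULT_CYCLE
    if _DEFAULT_CYCLE is None:
        _DEFAULT_CYCLE = _compute_default_cycle()
    clock, day = _DEFAULT_CYCLE
    i = int(round((clock_h % 24.0) / (DEFAULT_EPOCH_S / 3600.0))) % len(clock)
    return day[i].copy()
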