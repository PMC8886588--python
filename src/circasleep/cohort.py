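"""Synthetic participant generator with known ground truth.

No public dataset exists for the cohort the pipeline targets, so this module
emulates it end to end: each participant has a latent physiology (intrinsic
circadian period drawn from a shared distribution; wake drive drawn from a
group-specific distribution), a parametric light-availability environment,
and the recorded signals are produced by simulating the physiological model
under self-selected light and adding behavioral and measurement noise:

* lux      = availability sampled during model wake x log-normal sensor
             noise, at the sensor floor during sleep;
* activity = two-state negative-binomial counts (wake vs sleep);
* diary    = model sleep episodes + reporting jitter;
* weekly acrophases = circadian wake-propensity minimum + fixed offset +
             Gaussian noise, inside 48-h collection windows.

Every stochastic draw is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import (
    AcrophaseRecord,
    EpochSeries,
    ParticipantRecord,
    SleepEpisode,
    write_acrophases,
    write_diary,
    write_recording,
)
from .intervention import AvailableLightProfile, make_profile
from .model import ModelParams, onset_period, simulate

#: physiologically plausible range for drawn intrinsic periods (h)
TAU_RANGE = (23.9, 24.9)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Group sizes and the parameter distributions default to the study
    conditions the generator emulates: a shared intrinsic-period
    distribution of 24:13 +/- 0:11 h:m, group wake-drive distributions of
    -1.82 +/- 1.62 (cases) and 0.66 +/- 0.62 (controls), 6-week 2-min-epoch
    recordings, a dim (160/30 lux) case environment and a brighter (600/15
    lux) control environment.  Noise defaults are plausibility choices:
    15-min diary jitter, sigma = 0.3 log-normal lux noise, 30-min acrophase
    noise, negative-binomial activity counts (wake mean 250/epoch, sleep
    mean 10/epoch, dispersion 1.5).
    """

    n_cases: int = 20
    n_controls: int = 21
    days: int = 42
    epoch_length: int = 120
    seed: int = 0
    start: datetime = datetime(2024, 1, 1)
    # latent physiology
    tau_c_mean: float = 24.0 + 13.0 / 60.0
    tau_c_sd: float = 11.0 / 60.0
    delta_D_case_mean: float = -1.82
    delta_D_case_sd: float = 1.62
    delta_D_control_mean: float = 0.66
    delta_D_control_sd: float = 0.62
    # light environments (L_day, L_eve) lux
    case_light: tuple = (160.0, 30.0)
    control_light: tuple = (600.0, 15.0)
    # noise
    behavior_jitter_sd: float = 0.5   # h; day-to-day shift of availability
    diary_jitter_sd: float = 0.25     # h; episode reporting error
    lux_sigma: float = 0.3            # log-normal sigma on recorded lux
    lux_floor: float = 0.1            # sensor noise floor, lux
    acrophase_offset: float = 0.5     # h from CWPM to aMT6s acrophase
    acrophase_sd: float = 0.5         # h
    wake_counts: float = 250.0
    sleep_counts: float = 10.0
    count_dispersion: float = 1.5

    def __post_init__(self):
        if self.days < 28:
            raise ValueError("need days >= 28 for a meaningful cohort")
        for name in ("tau_c_sd", "delta_D_case_sd", "delta_D_control_sd",
                     "behavior_jitter_sd", "diary_jitter_sd", "lux_sigma",
                     "acrophase_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def evolve(self, **changes) -> "CohortConfig":
        return replace(self, **changes)


@dataclass
class GroundTruth:
    """Latent values behind one generated participant."""

    id: str
    group: str
    tau_c: float
    delta_D: float
    L_day: float
    L_eve: float
    acrophase_offset: float
    seed: int
    model_mean_duration: float
    model_onset_period: float


def _nb_counts(rng, mean, dispersion, size):
    """Negative-binomial counts with the given mean and dispersion r."""
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(float)


def _synthesize(
    config: CohortConfig,
    pid: str,
    group: str,
    tau_c: float,
    delta_D: float,
    profile: AvailableLightProfile,
    rng: np.random.Generator,
    seed: int,
):
    """Simulate one latent physiology under one light environment and wrap
    the noisy observables into a ParticipantRecord."""
    epd = 86400 // config.epoch_length
    n = config.days * epd
    eph = config.epoch_length / 3600.0
    start_clock = SleepEpisode.clock_hour(config.start)
    clock = (start_clock + np.arange(n) * eph) % 24.0
    day = (np.arange(n) * eph + start_clock) // 24.0
    shifts = rng.normal(0.0, config.behavior_jitter_sd, size=int(day[-1]) + 1)
    avail = profile.value(clock - shifts[day.astype(int)])

    params = ModelParams(tau_c=tau_c, delta_D=delta_D)
    sim = simulate(params, avail, start_time=config.start, mode="self_selected")
    wake = sim.wake[:-1]

    lux_noise = rng.lognormal(0.0, config.lux_sigma, size=n)
    lux = np.where(wake, np.maximum(avail, config.lux_floor), config.lux_floor)
    lux = lux * lux_noise
    activity = np.where(
        wake,
        _nb_counts(rng, config.wake_counts, config.count_dispersion, n),
        _nb_counts(rng, config.sleep_counts, config.count_dispersion, n),
    )
    recording = EpochSeries(config.start, config.epoch_length, activity, lux)

    # diary: model episodes + reporting jitter, kept ordered and in-span
    end = recording.end_time
    episodes = []
    for e in sim.episodes:
        on = e.onset + timedelta(hours=float(rng.normal(0, config.diary_jitter_sd)))
        off = e.offset + timedelta(hours=float(rng.normal(0, config.diary_jitter_sd)))
        on = max(on, config.start)
        off = min(off, end)
        if episodes and on < episodes[-1].offset:
            on = episodes[-1].offset + timedelta(minutes=1)
        if off <= on or (off - on) >= timedelta(hours=24):
            continue
        episodes.append(SleepEpisode(on, off, source="diary"))

    # weekly 48-h urine collection windows with one acrophase each
    cwpm = sim.cwpm_datetimes()
    acrophases = []
    for w in range(config.days // 7):
        w_start = config.start + timedelta(days=7 * w + 4, hours=8)
        w_end = w_start + timedelta(hours=48)
        if w_end > end:
            break
        for t in cwpm:
            acro = (
                t
                + timedelta(hours=config.acrophase_offset)
                + timedelta(hours=float(rng.normal(0, config.acrophase_sd)))
            )
            if w_start <= acro <= w_end:
                acrophases.append(AcrophaseRecord(acro, w_start, w_end))
                break

    record = ParticipantRecord(pid, group, recording, episodes, acrophases)
    try:
        period = sim.onset_period()
    except Exception:
        period = float("nan")
    model_dur = (
        float(np.mean([e.duration_hours for e in sim.episodes]))
        if sim.episodes
        else float("nan")
    )
    truth = GroundTruth(
        pid, group, tau_c, delta_D, profile.L_day, profile.L_eve,
        config.acrophase_offset, seed, model_dur, period,
    )
    return record, truth


def generate_participant(config: CohortConfig, group: str, seed: int):
    """Generate one participant: draw latent (tau_c, delta_D), simulate
    self-selected light exposure in the group's environment, add noise.
    Returns (ParticipantRecord, GroundTruth); identical seeds give
    bit-identical output."""
    if group not in ("case", "control"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    tau_c = float(np.clip(rng.normal(config.tau_c_mean, config.tau_c_sd), *TAU_RANGE))
    if group == "case":
        mean, sd = config.delta_D_case_mean, config.delta_D_case_sd
        light = config.case_light
    else:
        mean, sd = config.delta_D_control_mean, config.delta_D_control_sd
        light = config.control_light
    delta_D = float(np.clip(rng.normal(mean, sd), -3.8, 1.9))
    profile = make_profile(*light)
    return _synthesize(
        config, f"{group}{seed:04d}", group, tau_c, delta_D, profile, rng, seed
    )


def _participant_seed(config_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([config_seed, index]).generate_state(1)[0] % 2**31)


def generate_cohort(config: CohortConfig = None, out_dir=None):
    """Generate the full cohort with independent per-participant sub-seeds.

    The intrinsic-period draw depends only on (config.seed, participant
    index), never on group, so permuting group labels leaves the pooled
    tau_c distribution unchanged.  Returns (participants, ground_truth
    DataFrame); with ``out_dir`` also writes one CSV set per participant
    plus ``ground_truth.csv``.
    """
    config = config or CohortConfig()
    participants = []
    truths = []
    groups = ["case"] * config.n_cases + ["control"] * config.n_controls
    for i, group in enumerate(groups):
        seed = _participant_seed(config.seed, i)
        record, truth = generate_participant(config, group, seed)
        record.id = f"{group}{i:02d}"
        truth.id = record.id
        participants.append(record)
        truths.append(truth)
    table = pd.DataFrame([t.__dict__ for t in truths])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in participants:
            write_recording(rec.recording, out / f"{rec.id}_recording.csv")
            write_diary(rec.episodes, out / f"{rec.id}_diary.csv")
            write_acrophases(rec.acrophases, out / f"{rec.id}_acrophase.csv")
        table.to_csv(out / "ground_truth.csv", index=False)
    return participants, table


#: seasonal availability defaults: a short dim winter day with bright-ish
#: evenings indoors, and a long bright summer day with dim evenings
WINTER_PROFILE = AvailableLightProfile(
    160.0, 30.0, rise_time=8.0, peak_time=12.5, decline_time=17.0
)
SUMMER_PROFILE = AvailableLightProfile(
    1000.0, 10.0, rise_time=5.0, peak_time=13.0, decline_time=21.0
)


def seasonal_scenario(
    participant_seed: int = 0,
    config: CohortConfig = None,
    tau_c: float = 24.32,
    delta_D: float = -1.8,
    winter_profile: AvailableLightProfile = WINTER_PROFILE,
    summer_profile: AvailableLightProfile = SUMMER_PROFILE,
):
    """One latent physiology (long intrinsic period, low wake drive) recorded
    under a dim winter and a bright summer availability profile; only the
    light differs between the two records.  Returns
    ``{"winter": (record, truth), "summer": (record, truth)}``.
    """
    config = config or CohortConfig()
    out = {}
    for season, profile in (("winter", winter_profile), ("summer", summer_profile)):
        rng = np.random.default_rng([participant_seed, 0 if season == "winter" else 1])
        record, truth = _synthesize(
            config,
            f"seasonal_{season}",
            "case",
            tau_c,
            delta_D,
            profile,
            rng,
            participant_seed,
        )
        out[season] = (record, truth)
    return out
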