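"""Shared fixtures: small synthetic series and cached simulations."""

from datetime import datetime

import numpy as np
import pytest

from circasleep import EpochSeries, ModelParams, make_profile, simulate

START = datetime(2024, 1, 1)
EPOCH = 120
EPD = 86400 // EPOCH  # epochs per day


def make_series(activity, lux=None, missing=None, start=START, epoch=EPOCH):
    activity = np.asarray(activity, dtype=float)
    if lux is None:
        lux = np.zeros_like(activity)
    return EpochSeries(start, epoch, activity, lux, missing)


def square_wave(period_h, days, epoch=EPOCH, high=100.0, low=0.0, duty=0.5):
    """Square wave of the given period sampled at epoch resolution."""
    n = int(days * 86400 / epoch)
    t = np.arange(n) * epoch / 3600.0
    phase = np.mod(t, period_h) / period_h
    return np.where(phase < duty, high, low)


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def bright_profile():
    return make_profile(1000.0, 5.0)


@pytest.fixture(scope="session")
def entrained_sim(default_params, bright_profile):
    """42-day self-selected simulation of the default physiology under a
    regular bright availability profile (shared, read-only)."""
    return simulate(default_params, bright_profile, days=42.0, mode="self_selected")


@pytest.fixture(scope="session")
def dark_sim(default_params):
    """60-day constant-darkness simulation at tau_c = 24.2 (shared)."""
    lux = np.zeros(60 * EPD)
    return simulate(default_params, lux, mode="imposed")
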