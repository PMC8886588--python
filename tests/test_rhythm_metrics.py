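"""Folding period scan, circular statistics and light metrics."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circasleep import (
    DegenerateSignalError,
    InsufficientDataError,
    PeriodRangeError,
    SleepEpisode,
    circular_time_stats,
    fold_period_scan,
    light_metrics,
    sleep_timing_summary,
)
from conftest import EPD, START, make_series, square_wave

STEP_H = 120 / 3600.0


def brute_force_dominant_period(values, epoch_h, candidates):
    """Independent oracle: least-squares periodic-waveform fit.  For each
    candidate period the best-fitting periodic step waveform (one level per
    phase bin) is computed naively and the candidate with the smallest sum of
    squared residuals wins."""
    t = np.arange(len(values)) * epoch_h
    best_p, best_sse = None, np.inf
    for P in candidates:
        nbins = int(np.ceil(P / epoch_h))
        sse = 0.0
        phase_bin = np.floor((t % P) / epoch_h).astype(int)
        phase_bin[phase_bin >= nbins] = nbins - 1
        for b in range(nbins):
            vals = values[phase_bin == b]
            if len(vals):
                sse += float(np.sum((vals - vals.mean()) ** 2))
        if sse < best_sse:
            best_p, best_sse = P, sse
    return best_p


class TestFoldPeriodScan:
    def test_exact_square_wave_recovered(self):
        s = make_series(square_wave(24.0, 42))
        scan = fold_period_scan(s)
        assert scan.dominant_period == pytest.approx(24.0)
        assert scan.residual_variance.min() < 1e-9
        assert np.all((scan.residual_variance >= 0) & (scan.residual_variance <= 1.000001))

    @pytest.mark.parametrize("period", [24.0 + 38 / 60.0, 23.5])
    def test_noisy_imposed_period_within_one_step(self, period):
        rng = np.random.default_rng(11)
        sig = square_wave(period, 42, high=50.0, low=-50.0)
        s = make_series(np.maximum(0.0, sig + rng.normal(0, 50, sig.size) + 100.0))
        scan = fold_period_scan(s)
        assert abs(scan.dominant_period - period) <= STEP_H + 1e-9

    def test_white_noise_is_flat_with_low_depth(self):
        rng = np.random.default_rng(5)
        depths = []
        for seed in range(3):
            s = make_series(np.random.default_rng(seed).normal(0, 1, 42 * EPD) + 10)
            depths.append(fold_period_scan(s).depth)
        # min/median residual variance near 1: no real structure found
        assert min(depths) > 0.9

    def test_matches_brute_force_oracle_small_instance(self):
        rng = np.random.default_rng(3)
        epoch = 600  # 10-min epochs, 3 days
        n = 3 * 86400 // epoch
        t = np.arange(n) * epoch / 3600.0
        sig = 20 + 10 * (np.sin(2 * np.pi * t / 22.5) > 0) + rng.normal(0, 3, n)
        sig = np.maximum(0.0, sig)
        s = make_series(sig, epoch=epoch)
        scan = fold_period_scan(s, period_range=(21.0, 24.0))
        oracle = brute_force_dominant_period(sig, epoch / 3600.0, scan.candidate_periods)
        assert scan.dominant_period == pytest.approx(oracle)

    @given(a=st.floats(0.1, 50), b=st.floats(0, 100))
    @settings(max_examples=10, deadline=None)
    def test_scale_invariance(self, a, b):
        sig = square_wave(25.0, 21, high=3.0, low=1.0)
        base = fold_period_scan(make_series(sig)).residual_variance
        scaled = fold_period_scan(make_series(a * sig + b)).residual_variance
        np.testing.assert_allclose(scaled, base, atol=1e-8)

    def test_missing_epochs_excluded(self):
        sig = square_wave(24.0, 42)
        missing = np.zeros(sig.size, dtype=bool)
        missing[1000:3000] = True
        corrupted = sig.copy()
        corrupted[missing] = 12345.0  # masked garbage must not matter
        scan = fold_period_scan(make_series(corrupted, missing=missing))
        assert scan.dominant_period == pytest.approx(24.0)

    def test_errors(self):
        with pytest.raises(DegenerateSignalError):
            fold_period_scan(make_series(np.full(42 * EPD, 7.0)))
        with pytest.raises(PeriodRangeError):
            fold_period_scan(make_series(square_wave(24.0, 3)))  # span/3 < 28 h


class TestCircularStats:
    def test_wraparound_mean(self):
        st_ = circular_time_stats([23.5, 0.5])
        assert st_.mean_time == pytest.approx(0.0, abs=1e-9) or st_.mean_time == pytest.approx(24.0)

    def test_identical_times_zero_variance(self):
        st_ = circular_time_stats([8.0, 8.0, 8.0])
        assert st_.mean_time == pytest.approx(8.0)
        assert st_.circular_variance == pytest.approx(0.0, abs=1e-12)
        assert st_.circular_sd == pytest.approx(0.0, abs=1e-5)

    def test_uniform_times_near_zero_resultant(self):
        rng = np.random.default_rng(0)
        st_ = circular_time_stats(rng.uniform(0, 24, 10_000))
        assert st_.resultant_length < 0.03

    def test_antipodal_flagged_not_raised(self):
        st_ = circular_time_stats([3.0, 15.0])
        assert st_.mean_undefined
        assert math.isnan(st_.mean_time)

    def test_sd_formula(self):
        # two-point distribution at +/- 2 h: R = cos(2*pi*2/24)
        st_ = circular_time_stats([22.0, 2.0])
        R = math.cos(2 * math.pi * 2 / 24)
        assert st_.resultant_length == pytest.approx(R)
        assert st_.circular_sd == pytest.approx(
            (24 / (2 * math.pi)) * math.sqrt(-2 * math.log(R))
        )

    @given(
        center=st.floats(0, 24),
        offsets=st.lists(st.floats(-1.5, 1.5), min_size=2, max_size=20),
    )
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_linear_mean_on_tight_arc(self, center, offsets):
        times = [(center + o) % 24 for o in offsets]
        circ = circular_time_stats(times).mean_time
        linear = (center + np.mean(offsets)) % 24
        diff = min((circ - linear) % 24, (linear - circ) % 24)
        assert diff < 1 / 60.0

    def test_requires_two_times(self):
        with pytest.raises(InsufficientDataError):
            circular_time_stats([8.0])


class TestSleepTimingSummary:
    def _nightly(self, n, onset_h=23.0, dur=8.0):
        eps = []
        for i in range(n):
            on = START + timedelta(days=i, hours=onset_h)
            eps.append(SleepEpisode(on, on + timedelta(hours=dur)))
        return eps

    def test_regular_sleeper(self):
        s = sleep_timing_summary(self._nightly(42))
        assert s.duration_mean == pytest.approx(8.0)
        assert s.duration_sd == pytest.approx(0.0, abs=1e-12)
        assert s.offset.circular_variance == pytest.approx(0.0, abs=1e-12)
        assert s.mid_sleep.mean_time == pytest.approx(3.0)

    def test_alternating_onsets_closed_form(self):
        eps = []
        for i in range(20):
            on = START + timedelta(days=i, hours=22.0 if i % 2 == 0 else 26.0)
            eps.append(SleepEpisode(on, on + timedelta(hours=8)))
        s = sleep_timing_summary(eps)
        assert s.onset.mean_time == pytest.approx(0.0, abs=1e-9)
        R = math.cos(2 * math.pi * 2 / 24)
        assert s.onset.circular_sd == pytest.approx(
            (24 / (2 * math.pi)) * math.sqrt(-2 * math.log(R))
        )

    def test_jittered_sleeper_sd_recovery(self):
        rng = np.random.default_rng(1)
        eps = []
        for i in range(200):
            on = START + timedelta(days=i, hours=23.0 + rng.normal(0, 1.5))
            eps.append(SleepEpisode(on, on + timedelta(hours=8)))
        s = sleep_timing_summary(eps)
        # circular SD of a wrapped normal with sigma=1.5 h is ~1.5 h
        assert s.onset.circular_sd == pytest.approx(1.5, abs=0.25)

    def test_too_few_episodes(self):
        with pytest.raises(InsufficientDataError):
            sleep_timing_summary(self._nightly(1))


class TestLightMetrics:
    def test_constant_brightness_thresholds(self):
        n = 8 * EPD
        m600 = light_metrics(make_series(np.zeros(n), lux=np.full(n, 600.0)))
        assert m600.median_bright_hours == pytest.approx(24.0)
        m499 = light_metrics(make_series(np.zeros(n), lux=np.full(n, 499.0)))
        assert m499.median_bright_hours == pytest.approx(0.0)
        # strictly greater-than threshold
        m500 = light_metrics(make_series(np.zeros(n), lux=np.full(n, 500.0)))
        assert m500.median_bright_hours == pytest.approx(0.0)

    def test_half_day_bright_hand_computation(self):
        lux = square_wave(24.0, 8, high=1000.0, low=0.0)
        m = light_metrics(make_series(np.zeros_like(lux), lux=lux))
        assert m.median_bright_hours == pytest.approx(12.0)
        assert m.median_daily_log_lux == pytest.approx(0.5 * math.log(1001.0))
        assert m.median_daily_lux == pytest.approx(500.0)

    def test_monotone_in_lux(self):
        rng = np.random.default_rng(2)
        lux = rng.lognormal(3, 2, 9 * EPD)
        base = light_metrics(make_series(np.zeros_like(lux), lux=lux))
        add = lux.copy()
        add[::5] += 400.0
        more = light_metrics(make_series(np.zeros_like(add), lux=add))
        assert more.median_bright_hours >= base.median_bright_hours
        assert more.median_daily_lux >= base.median_daily_lux
        assert more.median_daily_log_lux >= base.median_daily_log_lux

    def test_all_masked_raises(self):
        n = 8 * EPD
        with pytest.raises(InsufficientDataError):
            light_metrics(
                make_series(np.zeros(n), lux=np.ones(n), missing=np.ones(n, bool))
            )
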