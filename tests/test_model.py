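"""The coupled sleep-wake/pacemaker system: derivatives, simulation,
phase markers and period read-outs."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from circasleep import (
    InsufficientDataError,
    ModelParams,
    ModelState,
    SleepEpisode,
    free_running_period,
    onset_period,
    simulate,
)
from circasleep import model as model_mod
from circasleep._engine import _rhs
from circasleep.model import circadian_drive, cwpm_times
from conftest import EPD, START


def random_states(rng, n):
    for _ in range(n):
        yield np.array(
            [
                rng.uniform(-12, 2),
                rng.uniform(-12, 2),
                rng.uniform(0, 25),
                rng.uniform(-1.2, 1.2),
                rng.uniform(-1.2, 1.2),
                rng.uniform(0, 1),
            ]
        )


class TestDerivatives:
    def test_dark_limit(self, default_params):
        """With I = 0 the photic drive vanishes: dn/dt = -60*beta*n and the
        pacemaker reduces to the autonomous oscillator."""
        y = np.array([-2.0, 0.5, 14.0, 0.3, -0.8, 0.4])
        d = model_mod.derivatives(y, 0.0, default_params, I=0.0)
        p = default_params
        assert d[5] == pytest.approx(-60.0 * p.beta * y[5])
        # autonomous pacemaker rates (B = 0)
        x, xc = y[3], y[4]
        pi12 = np.pi / 12
        dx = pi12 * (xc + p.mu_p * (x / 3 + 4 * x**3 / 3 - 256 * x**7 / 105))
        dxc = pi12 * (-x * (24 / (p.f * p.tau_c)) ** 2)
        assert d[3] == pytest.approx(dx)
        assert d[4] == pytest.approx(dxc)

    def test_photoreceptor_saturation(self, default_params):
        """At n = 1 the activation term of dn/dt vanishes regardless of I."""
        y = np.array([-2.0, 0.5, 14.0, 0.3, -0.8, 1.0])
        d = model_mod.derivatives(y, 0.0, default_params, I=5000.0)
        assert d[5] == pytest.approx(-60.0 * default_params.beta)

    def test_jacobian_central_difference_vs_complex_step(self, default_params):
        """Numerical Jacobian by central differences matches the complex-step
        oracle to 1e-6 relative."""
        rng = np.random.default_rng(42)
        for y in random_states(rng, 3):
            J_cs = np.empty((6, 6))
            J_cd = np.empty((6, 6))
            for j in range(6):
                h = 1e-30
                yc = y.astype(complex)
                yc[j] += 1j * h
                J_cs[:, j] = model_mod.derivatives(yc, 0.0, default_params, 150.0).imag / h
                e = 1e-6 * max(1.0, abs(y[j]))
                yp, ym = y.copy(), y.copy()
                yp[j] += e
                ym[j] -= e
                J_cd[:, j] = (
                    model_mod.derivatives(yp, 0.0, default_params, 150.0)
                    - model_mod.derivatives(ym, 0.0, default_params, 150.0)
                ) / (2 * e)
            scale = np.abs(J_cs) + 1.0
            assert np.max(np.abs(J_cd - J_cs) / scale) < 1e-6

    def test_engine_rhs_matches_reference(self, default_params):
        rng = np.random.default_rng(7)
        pp = default_params.to_array()
        for y in random_states(rng, 5):
            for I in (0.0, 30.0, 900.0):
                np.testing.assert_allclose(
                    _rhs(y, I, pp),
                    model_mod.derivatives(y, 0.0, default_params, I),
                    rtol=1e-12,
                )

    def test_negative_light_rejected(self, default_params):
        with pytest.raises(ValueError):
            model_mod.derivatives(np.zeros(6), 0.0, default_params, -1.0)


class TestSimulate:
    def test_entrained_default_one_episode_per_day(self, entrained_sim):
        eps = entrained_sim.episodes_after(24.0 * 14)
        days = 42 - 14
        assert days - 2 <= len(eps) <= days
        durs = [e.duration_hours for e in eps]
        assert 7.0 < np.mean(durs) < 9.5
        assert entrained_sim.onset_period() == pytest.approx(24.0, abs=2 / 60)
        assert entrained_sim.dropped_episodes == 0

    def test_wake_indicator_consistent_with_episodes(self, entrained_sim):
        sim = entrained_sim
        mid = sim.episodes[5].onset + (sim.episodes[5].offset - sim.episodes[5].onset) / 2
        i = int(((mid - sim.start_time).total_seconds() / sim.epoch_length))
        assert not sim.wake[i]
        wake_mid = sim.episodes[5].offset + timedelta(hours=6)
        j = int(((wake_mid - sim.start_time).total_seconds() / sim.epoch_length))
        assert sim.wake[j]

    def test_free_running_sleep_period_tracks_tau(self, dark_sim):
        """In darkness the sleep-wake cycle locks to the pacemaker: the onset
        period approximates tau_c."""
        per = onset_period(dark_sim.episodes_after(24.0 * 14))
        assert per == pytest.approx(24.2, abs=0.05)

    def test_sleep_duration_decreases_with_wake_drive(self, bright_profile):
        durs = []
        for dd in (-1.0, 0.0, 1.0):
            sim = simulate(
                ModelParams(delta_D=dd), bright_profile, days=28, mode="self_selected"
            )
            eps = sim.episodes_after(24.0 * 14)
            durs.append(np.mean([e.duration_hours for e in eps]))
        assert durs[0] > durs[1] > durs[2]

    def test_state_bounds_long_run(self, default_params, bright_profile):
        sim = simulate(default_params, bright_profile, days=180, mode="self_selected")
        n = sim.states[:, 5]
        assert np.all((n >= 0.0) & (n <= 1.0))
        assert np.all(np.abs(sim.states[:, 3]) < 3.0)
        assert np.all(np.abs(sim.states[:, 4]) < 3.0)

    def test_substep_halving_moves_onsets_under_one_minute(
        self, default_params, bright_profile
    ):
        s1 = simulate(default_params, bright_profile, days=21)
        s2 = simulate(default_params, bright_profile, days=21, n_sub=48)
        a = [e.onset for e in s1.episodes_after(24.0 * 7)][:10]
        b = [e.onset for e in s2.episodes_after(24.0 * 7)][:10]
        for x, y in zip(a, b):
            assert abs((x - y).total_seconds()) < 60.0

    def test_bad_mode_rejected(self, default_params, bright_profile):
        with pytest.raises(ValueError):
            simulate(default_params, bright_profile, days=14, mode="forced")


class TestFreeRunningPeriod:
    @pytest.mark.parametrize("tau", [24.0, 24.5])
    def test_pacemaker_period_equals_tau(self, tau):
        fr = free_running_period(ModelParams(tau_c=tau), days=60)
        assert fr == pytest.approx(tau, abs=0.02)


class TestCwpm:
    def test_analytic_cosine_input(self, default_params):
        """With x = cos, x_c = sin imposed, the drive minimum matches the
        closed-form minimum of C."""
        t = np.arange(0, 72, 1 / 30.0)
        states = np.zeros((len(t), 6))
        states[:, 3] = np.cos(2 * np.pi * t / 24)
        states[:, 4] = np.sin(2 * np.pi * t / 24)
        sim = model_mod.SimResult(
            params=default_params,
            start_time=START,
            epoch_length=120,
            t_hours=t,
            states=states,
            wake=np.ones(len(t), bool),
            episodes=[],
            transition_times=np.array([]),
            transition_dirs=np.array([]),
        )
        got = cwpm_times(sim)
        # C = (1 + cx cos(th) + cxc sin(th))/2 is minimal at
        # th = pi + atan2(cxc, cx)  (mod 2 pi)
        p = default_params
        th_min = (np.pi + np.arctan2(p.cxc, p.cx)) % (2 * np.pi)
        expected_first = th_min * 24 / (2 * np.pi)
        assert got[0] == pytest.approx(expected_first, abs=0.05)
        np.testing.assert_allclose(np.diff(got), 24.0, atol=0.05)

    def test_entrained_spacing(self, entrained_sim):
        c = entrained_sim.cwpm_hours()
        c = c[c > 24.0 * 14]
        assert len(c) >= 25
        np.testing.assert_allclose(np.diff(c), 24.0, atol=0.1)

    def test_free_run_spacing(self, default_params):
        sim = simulate(
            ModelParams(tau_c=24.5), np.zeros(50 * EPD), mode="imposed"
        )
        c = sim.cwpm_hours()
        c = c[c > 24.0 * 10]
        assert np.mean(np.diff(c)) == pytest.approx(24.5, abs=0.1)

    def test_non_oscillatory_returns_empty(self, default_params):
        t = np.arange(0, 72, 1 / 30.0)
        states = np.zeros((len(t), 6))
        sim = model_mod.SimResult(
            params=default_params,
            start_time=START,
            epoch_length=120,
            t_hours=t,
            states=states,
            wake=np.ones(len(t), bool),
            episodes=[],
            transition_times=np.array([]),
            transition_dirs=np.array([]),
        )
        assert len(cwpm_times(sim)) == 0


class TestOnsetPeriod:
    def _episodes(self, drift_min_per_day=0.0, n=21):
        eps = []
        for i in range(n):
            on = START + timedelta(days=i, hours=23.0, minutes=drift_min_per_day * i)
            eps.append(SleepEpisode(on, on + timedelta(hours=8)))
        return eps

    def test_nightly_onsets(self):
        assert onset_period(self._episodes(0.0)) == pytest.approx(24.0)

    def test_drifting_onsets(self):
        assert onset_period(self._episodes(30.0)) == pytest.approx(24.5)

    def test_concordance_with_fold_scan_of_wake_indicator(self, dark_sim):
        from circasleep import EpochSeries, fold_period_scan

        per = onset_period(dark_sim.episodes_after(24.0 * 14))
        wake = dark_sim.wake[:-1].astype(float)
        series = EpochSeries(dark_sim.start_time, 120, wake, np.zeros_like(wake))
        scan = fold_period_scan(series, period_range=(23.0, 26.0))
        assert abs(per - scan.dominant_period) <= 0.05

    def test_too_few(self):
        with pytest.raises(InsufficientDataError):
            onset_period(self._episodes(n=5))
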