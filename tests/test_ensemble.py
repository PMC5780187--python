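"""Ensemble statistics: grouping, settling, instability, selection, fits."""

import math

import numpy as np
import pytest

from hoverfall.ensemble import (
    fit_onset_distribution,
    group_mean_series,
    instability_onset,
    onset_group_label,
    run_ensemble,
    select_trials,
    settling_time,
)
from hoverfall.simulate import FallTrajectory, simulate_fall

TS = 1.0 / 1600.0


def _make_traj(theta_p, vz=None, omega_x=None, onset=0.1, ts=TS):
    n = len(theta_p)
    z = np.zeros(n)
    return FallTrajectory(
        t=np.arange(n) * ts, x=np.zeros(n), z=z,
        vx=np.zeros(n), vz=np.zeros(n) if vz is None else np.asarray(vz, float),
        theta_p=np.asarray(theta_p, float), theta_p_dot=np.zeros(n),
        f_mag=np.zeros(n), lift=np.zeros(n), thrust=np.zeros(n),
        omega_x=np.zeros(n) if omega_x is None else np.asarray(omega_x, float),
        omega_z=np.zeros(n),
        onset_time=onset, variant="basic", crashed=False, crash_time=None,
    )


class TestGrouping:
    def test_bins_are_exhaustive_and_disjoint(self):
        for onset in np.linspace(0.075, 0.150, 16):
            assert onset_group_label(float(onset)) is not None
        assert onset_group_label(0.099) == "75-100ms"
        assert onset_group_label(0.100) == "100-125ms"
        assert onset_group_label(0.150) == "125-150ms"
        assert onset_group_label(0.160) is None

    def test_group_means_are_permutation_invariant(self, config, improved_gains):
        trajs = [
            simulate_fall(config, improved_gains, o, "improved", horizon=0.4)
            for o in (0.08, 0.09, 0.11, 0.13, 0.14)
        ]
        a = group_mean_series(trajs, TS)
        b = group_mean_series(trajs[::-1], TS)
        assert set(a) == set(b)
        for label in a:
            assert np.array_equal(a[label]["theta_p"], b[label]["theta_p"])


class TestSettlingTime:
    def test_constant_series_settles_immediately(self):
        assert settling_time(np.ones(100), TS, onset=0.0) == 0.0

    def test_exponential_decay_matches_analytic_first_crossing(self):
        # theta(t) = theta0*exp(-t/tau): enters the 0.1*|theta0| band (around
        # a final value ~0) at t = tau*ln(10) and never leaves
        tau, theta0 = 0.05, 1.0
        t = np.arange(0, 1.0, TS)
        series = theta0 * np.exp(-t / tau)
        st = settling_time(series, TS, onset=0.0, band=0.1 * theta0)
        final = series[-1]
        expected = tau * math.log(theta0 / (0.1 * theta0 + final))
        assert st == pytest.approx(expected, abs=2 * TS)

    def test_never_settling_returns_none(self):
        t = np.arange(0, 0.5, TS)
        assert settling_time(np.sin(40 * t), TS, onset=0.0, band=0.05) is None


class TestInstabilityDetector:
    def test_pitch_crossing_detected_at_exact_sample(self):
        theta = np.zeros(800)
        theta[500:] = 2.0  # exceeds pi/2 at sample 500
        tr = _make_traj(theta, omega_x=np.full(800, 0.0))
        assert instability_onset(tr) == pytest.approx(500 * TS)

    def test_of_error_growth_detected(self):
        n = 800
        omega_x = np.full(n, -0.5)
        omega_x[600:] = -8.0  # error grows ~15-fold
        tr = _make_traj(np.zeros(n), omega_x=omega_x)
        assert instability_onset(tr) == pytest.approx(600 * TS)

    def test_stable_run_returns_none(self, config, improved_gains):
        tr = simulate_fall(config, improved_gains, 0.1, "improved", horizon=1.0)
        assert instability_onset(tr) is None


class TestSelection:
    def test_late_onset_excluded(self):
        tr = _make_traj(np.zeros(600), vz=np.ones(600), onset=0.160)
        assert select_trials([tr]) == []

    def test_recovering_trial_truncated_at_first_positive_vz(self):
        n = 800
        vz = np.full(n, -1.0)
        k_pos = int(round(0.21 / TS))
        vz[k_pos:] = 0.5
        tr = _make_traj(np.zeros(n), vz=vz, onset=0.100)
        kept = select_trials([tr])
        assert len(kept) == 1
        assert kept[0].t[-1] == pytest.approx(k_pos * TS)

    def test_never_recovering_trial_excluded(self):
        tr = _make_traj(np.zeros(900), vz=np.full(900, -1.0), onset=0.100)
        assert select_trials([tr]) == []


class TestOnsetFits:
    def test_constant_onsets_flagged_degenerate(self):
        fits = fit_onset_distribution(np.full(10, 0.103))
        assert fits["normal"]["implied_mean"] == pytest.approx(0.103)
        assert fits["normal"]["degenerate"]

    def test_lognormal_parameter_recovery(self, rng):
        mu, sigma = math.log(0.1), 0.3
        sample = rng.lognormal(mu, sigma, size=10_000)
        fits = fit_onset_distribution(sample)
        true_mean = math.exp(mu + sigma**2 / 2)
        se = sample.std() / math.sqrt(sample.size)
        assert abs(fits["lognormal"]["implied_mean"] - true_mean) < 2 * se

    def test_normal_and_lognormal_agree_on_near_symmetric_data(self, rng):
        sample = rng.normal(0.103, 0.005, size=10_000)  # tight, near-symmetric
        fits = fit_onset_distribution(sample)
        assert fits["normal"]["implied_mean"] == pytest.approx(
            fits["lognormal"]["implied_mean"], rel=0.01
        )

    def test_nonpositive_onsets_rejected(self):
        with pytest.raises(ValueError):
            fit_onset_distribution(np.array([0.1, -0.1, 0.1, 0.1, 0.1]))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_onset_distribution(np.array([0.1, 0.1]))


class TestRunEnsemble:
    def test_same_seed_is_bitwise_reproducible(self, config, basic_gains):
        a = run_ensemble(5, config, basic_gains, "basic", seed=42, horizon=0.8)
        b = run_ensemble(5, config, basic_gains, "basic", seed=42, horizon=0.8)
        assert np.array_equal(a.onsets, b.onsets)
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert np.array_equal(ta.theta_p, tb.theta_p)
        assert a.instability_onsets == b.instability_onsets

    def test_single_run_reduces_to_simulate_fall(self, config, basic_gains):
        res = run_ensemble(1, config, basic_gains, "basic", seed=7, horizon=0.8)
        direct = simulate_fall(
            config, basic_gains, float(res.onsets[0]), "basic", horizon=0.8
        )
        assert np.array_equal(res.trajectories[0].theta_p, direct.theta_p)

    def test_crash_fraction_is_a_fraction(self, config, improved_gains):
        res = run_ensemble(6, config, improved_gains, "improved", seed=3,
                           horizon=1.5)
        assert 0.0 <= res.crash_fraction <= 1.0

    def test_basic_variant_always_detects_instability(self, config, basic_gains):
        # structural claim: forward-OF regulation alone cannot hold the fall
        res = run_ensemble(8, config, basic_gains, "basic", seed=11, horizon=3.0)
        assert all(v is not None for v in res.instability_onsets)
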