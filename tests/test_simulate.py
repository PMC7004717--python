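"""Simulator: dwell statistics, source model, cohort, depth monotonicity."""

import numpy as np
import pytest

from cai import (
    DepthProfile,
    SimConfig,
    ValidationError,
    alpha_kernel,
    compute_cai,
    sample_state_sequence,
    simulate_cohort,
    simulate_eeg,
    source_signal,
    surgery_profile,
    synthetic_bis,
)
from helpers import seed_from


class TestStateSequence:
    def test_awake_is_mostly_up(self):
        # analytic mean up-fraction at d=0: 6.05 / (6.05 + 0.01)
        fracs = [
            sample_state_sequence(0.0, SimConfig(), 60, np.random.default_rng(s)).mean()
            for s in range(20)
        ]
        assert np.mean(fracs) > 0.9

    def test_deep_is_mostly_down(self):
        fracs = [
            sample_state_sequence(1.0, SimConfig(), 60, np.random.default_rng(s)).mean()
            for s in range(20)
        ]
        assert np.mean(fracs) < 0.2

    def test_up_fraction_decreases_with_depth(self):
        means = []
        for d in [0.1, 0.5, 0.9]:
            fr = [
                sample_state_sequence(d, SimConfig(), 60, np.random.default_rng(s)).mean()
                for s in range(20)
            ]
            means.append(np.mean(fr))
        assert means[0] > means[1] > means[2]

    def test_deterministic_under_fixed_seed(self):
        a = sample_state_sequence(0.5, SimConfig(), 30, np.random.default_rng(7))
        b = sample_state_sequence(0.5, SimConfig(), 30, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_depth_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sample_state_sequence(1.5, SimConfig(), 10, np.random.default_rng(0))


class TestSourceSignal:
    def test_all_down_gives_silence(self):
        out = source_signal(np.zeros(1000, dtype=int), SimConfig(),
                            np.random.default_rng(0))
        assert np.all(out == 0)

    def test_single_spike_reproduces_alpha_kernel(self):
        # kernel peak psp_amp at t = psp_tau, here on the sample grid
        cfg = SimConfig(psp_tau=4 / 128, psp_amp=5.0, firing_rate_up=1.0)
        kernel = alpha_kernel(cfg)
        assert kernel[4] == pytest.approx(cfg.psp_amp, rel=1e-12)
        assert kernel.max() == pytest.approx(cfg.psp_amp, rel=1e-12)
        spikes = np.zeros(100)
        spikes[0] = 1
        out = np.convolve(spikes, kernel)[:100]
        np.testing.assert_allclose(out[: kernel.size], kernel)

    def test_output_linear_in_psp_amp(self):
        states = np.ones(2000, dtype=int)
        a = source_signal(states, SimConfig(psp_amp=3.0), np.random.default_rng(3))
        b = source_signal(states, SimConfig(psp_amp=6.0), np.random.default_rng(3))
        np.testing.assert_allclose(b, 2 * a, rtol=1e-12)


class TestSimulateEeg:
    def test_deterministic_under_fixed_seed(self):
        prof = DepthProfile([0, 60], [0.5, 0.5])
        r1, t1 = simulate_eeg(prof, SimConfig(seed=5))
        r2, t2 = simulate_eeg(prof, SimConfig(seed=5))
        assert np.array_equal(r1.samples, r2.samples)
        assert np.array_equal(t1.values, t2.values)

    def test_silent_config_gives_all_zero_record(self):
        prof = DepthProfile([0, 20], [0.5, 0.5])
        rec, _ = simulate_eeg(
            prof, SimConfig(n_sources=0, noise_pink=0, noise_white=0)
        )
        assert np.all(rec.samples == 0)

    def test_delta_power_fraction_increases_with_depth(self):
        from scipy.signal import periodogram

        fracs = []
        for d in (0.0, 0.9):
            rec, _ = simulate_eeg(
                DepthProfile([0, 60], [d, d]), SimConfig(seed=21)
            )
            f, P = periodogram(rec.samples, fs=rec.fs)
            fracs.append(P[(f > 0) & (f <= 4)].sum() / P[f > 0].sum())
        assert fracs[1] > fracs[0]

    def test_deep_record_has_suppression_gaps_and_bursts(self, deep_record):
        # burst-suppression morphology: rectified-envelope spread is large
        env = np.abs(deep_record.samples)
        q10, q90 = np.quantile(env, [0.10, 0.90])
        assert q90 > 8 * max(q10, 1e-9)

    def test_truth_trace_on_index_cadence(self):
        prof = DepthProfile([0, 100], [0.0, 1.0])
        _, truth = simulate_eeg(prof, SimConfig(seed=2), index_dt=2.0)
        assert len(truth) == 50
        np.testing.assert_allclose(truth.values, prof.at(truth.times))

    def test_short_profile_rejected(self):
        with pytest.raises(ValidationError):
            simulate_eeg(DepthProfile([0, 5], [0, 0]), SimConfig())


class TestCohort:
    def test_cohort_size_and_adult_ages(self):
        cohort = simulate_cohort(
            6, SimConfig(seed=3), maintenance_s=60, awake_s=30, recovery_s=30
        )
        assert len(cohort) == 6
        assert all(meta.age >= 18 for meta, _, _ in cohort)
        assert all(meta.bmi > 15 for meta, _, _ in cohort)

    def test_same_master_seed_reproduces_cohort(self):
        kw = dict(maintenance_s=60, awake_s=30, recovery_s=30)
        c1 = simulate_cohort(3, SimConfig(seed=9), **kw)
        c2 = simulate_cohort(3, SimConfig(seed=9), **kw)
        for (m1, r1, p1), (m2, r2, p2) in zip(c1, c2):
            assert m1 == m2
            assert np.array_equal(r1.samples, r2.samples)
            assert np.array_equal(p1.d, p2.d)

    def test_template_endpoints_near_awake(self, rng):
        prof = surgery_profile(rng)
        assert prof.d[0] < 0.2 and prof.d[-1] < 0.2
        assert prof.d.max() >= 0.3  # reaches anesthetic depth

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(0, SimConfig())

    def test_synthetic_bis_tracks_inverted_depth(self, rng):
        prof = surgery_profile(rng)
        bis = synthetic_bis(prof, rng)
        assert bis.values.min() >= 0 and bis.values.max() <= 100
        r = np.corrcoef(bis.values, 1 - prof.at(bis.times))[0, 1]
        assert r > 0.95


class TestMonotoneValidity:
    def test_mean_cai_strictly_decreases_with_depth(self):
        """Core fitness-for-purpose: deeper simulated anesthesia, lower CAI."""
        from scipy.stats import spearmanr

        depths = [0.1, 0.3, 0.5, 0.7, 0.9]
        means = []
        for di, d in enumerate(depths):
            vals = []
            for si in range(8):
                rec, _ = simulate_eeg(
                    DepthProfile([0, 60], [d, d]),
                    SimConfig(seed=seed_from(99, di, si)),
                )
                vals.append(compute_cai(rec).values.mean())
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))
        assert spearmanr(depths, means).statistic <= -0.9
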