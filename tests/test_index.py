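"""CAI core: epoching, adaptive threshold, peak density, pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cai import (
    CaiParams,
    EEGRecord,
    EpochingParams,
    ThresholdParams,
    ValidationError,
    adaptive_threshold,
    compute_cai,
    low_freq_magnitude,
    moving_average,
    peak_density,
    segment_epochs,
)


class TestSegmentEpochs:
    @pytest.mark.parametrize(
        "n,epoch_len,step,expected",
        [
            (1280, 256, 256, 5),
            (1280, 256, 128, 9),  # floor((1280-256)/128)+1
            (512, 512, 256, 1),
            (513, 512, 256, 1),  # trailing partial window discarded
        ],
    )
    def test_epoch_count(self, n, epoch_len, step, expected, rng):
        rec = EEGRecord(rng.normal(size=n), fs=128)
        eps = segment_epochs(rec, EpochingParams(epoch_len, step))
        assert len(eps) == expected

    def test_too_short_record_rejected(self, rng):
        rec = EEGRecord(rng.normal(size=255), fs=128)
        with pytest.raises(ValidationError, match="shorter"):
            segment_epochs(rec, EpochingParams(256, 256))

    def test_center_times(self, rng):
        rec = EEGRecord(rng.normal(size=1280), fs=128, t0=5.0)
        eps = segment_epochs(rec, EpochingParams(256, 256))
        assert eps[0].t_center == pytest.approx(5.0 + 128 / 128)
        assert eps[1].t_center == pytest.approx(5.0 + (256 + 128) / 128)


class TestLowFreqMagnitude:
    def test_zero_epoch_gives_zero(self):
        assert low_freq_magnitude(np.zeros(256), M=5) == 0.0

    def test_on_bin_cosine_closed_form(self):
        n = np.arange(256)
        x = np.cos(2 * np.pi * 1 * n / 256)
        assert low_freq_magnitude(x, M=1) == pytest.approx(128.0, abs=1e-9)

    def test_high_frequency_cosine_invisible_to_low_bins(self):
        n = np.arange(256)
        x = np.cos(2 * np.pi * 40 * n / 256)
        assert low_freq_magnitude(x, M=8) == pytest.approx(0.0, abs=1e-9)

    def test_m_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            low_freq_magnitude(np.zeros(256), M=128)
        with pytest.raises(ValidationError):
            low_freq_magnitude(np.zeros(256), M=0)


class TestAdaptiveThreshold:
    def test_zero_epoch_gives_zero(self):
        assert adaptive_threshold(np.zeros(256), ThresholdParams(K=2, M=1)) == 0.0

    def test_on_bin_cosine_equals_amplitude(self):
        # K=2, M=1: T = 2*(N/2)*A/N = A
        n = np.arange(256)
        for A in (1.0, 7.5):
            x = A * np.cos(2 * np.pi * n / 256)
            T = adaptive_threshold(x, ThresholdParams(K=2, M=1))
            assert T == pytest.approx(A, abs=1e-9)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_positive_homogeneity_and_dc_invariance(self, seed, c):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 10, 256)
        params = ThresholdParams(K=3.0, M=8)
        t1 = adaptive_threshold(x, params)
        assert adaptive_threshold(c * x, params) == pytest.approx(c * t1, rel=1e-9)
        assert adaptive_threshold(x + 42.0, params) == pytest.approx(t1, rel=1e-6, abs=1e-9)


class TestPeakDensity:
    def test_direct_count_example(self):
        assert peak_density(np.array([1.0, -3.0, 2.0, 0.5]), 1.5) == 0.5

    def test_threshold_extremes(self, rng):
        x = rng.normal(1.0, 1.0, 256)
        x[x == 0] = 0.5
        assert peak_density(x, 0.0) == 1.0
        assert peak_density(x, np.abs(x).max() + 1) == 0.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            peak_density(np.zeros(8), -0.1)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            x = rng.normal(0, rng.uniform(0.5, 30), 256)
            t = rng.uniform(0, 40)
            expected = sum(1 for v in x if abs(v) > t) / 256
            assert peak_density(x, t) == expected

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_non_increasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 10, 256)
        ts = np.sort(rng.uniform(0, 30, 10))
        ds = [peak_density(x, t) for t in ts]
        assert all(a >= b for a, b in zip(ds, ds[1:]))


class TestComputeCai:
    def test_all_zero_record_scores_zero(self):
        rec = EEGRecord(np.zeros(128 * 30), fs=128)
        series = compute_cai(rec)
        assert np.all(series.values == 0.0)

    def test_smoothing_width_one_is_identity(self, awake_record):
        p1 = CaiParams(smooth_epochs=1)
        raw = compute_cai(awake_record, p1)
        # manual composition oracle: epochs -> threshold -> density -> scale
        eps = segment_epochs(awake_record, p1.epoching)
        manual = []
        for e in eps:
            T = adaptive_threshold(e, p1.threshold)
            manual.append(100.0 * peak_density(e, T))
        np.testing.assert_allclose(raw.values, manual, atol=1e-9)

    def test_pipeline_equals_manual_composition_with_smoothing(self, awake_record):
        p = CaiParams()
        eps = segment_epochs(awake_record, p.epoching)
        dens = np.array(
            [peak_density(e, adaptive_threshold(e, p.threshold)) for e in eps]
        )
        manual = np.clip(100.0 * moving_average(dens, p.smooth_epochs), 0, 100)
        np.testing.assert_allclose(compute_cai(awake_record, p).values, manual, 1e-12)

    def test_awake_scores_above_deep(self, awake_record, deep_record):
        assert compute_cai(awake_record).values.mean() > compute_cai(
            deep_record
        ).values.mean()

    def test_white_noise_above_slow_burst_surrogate(self, rng):
        white = EEGRecord(rng.normal(0, 15, 128 * 60), fs=128)
        # slow-wave bursts separated by near-isoelectric gaps
        t = np.arange(128 * 60) / 128.0
        gate = (np.sin(2 * np.pi * t / 4.0) > 0.4).astype(float)
        burst = 60 * np.sin(2 * np.pi * 2.0 * t) * gate + rng.normal(0, 1, t.size)
        deep = EEGRecord(burst, fs=128)
        assert compute_cai(white).values.mean() > compute_cai(deep).values.mean()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_output_in_display_range_and_deterministic(self, seed):
        rng = np.random.default_rng(seed)
        rec = EEGRecord(rng.normal(0, rng.uniform(1, 80), 128 * 20), fs=128)
        a = compute_cai(rec)
        b = compute_cai(rec)
        assert np.array_equal(a.values, b.values)
        assert a.values.min() >= 0 and a.values.max() <= 100
        assert a.name == "CAI"
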