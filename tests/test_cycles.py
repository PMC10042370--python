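"""Cycle segmentation, variability, amplitude and velocity metrics."""

import numpy as np
import pytest

import lumovar as lv
from lumovar.cycles import (
    CycleError,
    align_cycles,
    amplitude,
    cycl_sd,
    detect_cycles,
    mean_sd,
    normalize_cycles,
    select_analysis_cycles,
    velocity,
    N_PHASE_POINTS,
)


class TestDetectCycles:
    def test_noiseless_trial_peaks_match_ground_truth(self, noiseless_trial):
        series, truth = noiseless_trial
        peaks = detect_cycles(series.flexion_extension, expected_count=45)
        assert peaks.size == 45
        err = np.abs(peaks / series.sample_rate - truth.peak_times)
        assert err.max() <= 1.01 / series.sample_rate

    def test_jittered_trial_peaks_match_ground_truth(self):
        series, truth = lv.generate_angle_trial(
            lv.TrialConfig(seed=3, temporal_jitter_sd=0.12))
        peaks = detect_cycles(series.flexion_extension, expected_count=45)
        err = np.abs(peaks / series.sample_rate - truth.peak_times)
        assert err.max() <= 1.5 / series.sample_rate

    def test_constant_signal_rejected(self):
        with pytest.raises(CycleError, match="constant"):
            detect_cycles(np.ones(1000))

    def test_expected_count_mismatch_lists_peaks(self, noiseless_trial):
        series, _ = noiseless_trial
        with pytest.raises(CycleError, match="expected 44"):
            detect_cycles(series.flexion_extension, expected_count=44)


class TestSelectAnalysisCycles:
    def test_46_peaks_keep_cycles_6_to_45(self):
        peaks = np.arange(46) * 260
        sel = select_analysis_cycles(peaks, 40)
        assert sel.size == 41
        assert sel[0] == peaks[5] and sel[-1] == peaks[45]

    def test_exactly_41_peaks_keep_all(self):
        peaks = np.arange(41) * 260
        assert np.array_equal(select_analysis_cycles(peaks, 40), peaks)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(CycleError, match="40 required"):
            select_analysis_cycles(np.arange(30) * 260, 40)


class TestCyclSd:
    def test_constant_durations_zero(self):
        assert cycl_sd(np.full(40, 2.6)) == 0.0

    def test_two_value_closed_form(self):
        # SD of {2.5, 2.7} with n-1 denominator = sqrt(2 * 0.01 / 1)
        assert cycl_sd([2.5, 2.7]) == pytest.approx(np.sqrt(0.02), abs=1e-12)

    def test_single_duration_rejected(self):
        with pytest.raises(CycleError):
            cycl_sd([2.6])

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(2, 3, 40)
        assert cycl_sd(d) == pytest.approx(cycl_sd(d + 10.0), abs=1e-12)


class TestNormalizeCycles:
    def test_idempotent_on_101_uniform_samples(self):
        rng = np.random.default_rng(1)
        angles = rng.normal(size=(101, 3)).cumsum(axis=0)
        out = normalize_cycles(angles, [0, 100])
        assert np.abs(out[0] - angles).max() < 1e-12

    def test_linear_ramp_stays_linear(self):
        angles = np.linspace(0, 1, 60)[:, None] * np.array([[1.0, 2.0, -3.0]])
        out = normalize_cycles(angles, [0, 59])
        expected = np.linspace(0, 1, N_PHASE_POINTS)[:, None] * np.array([[1.0, 2.0, -3.0]])
        assert np.abs(out[0] - expected).max() < 1e-12

    def test_time_warp_invariance(self):
        # same shape traversed at half/double duration -> identical normalized cycles
        def make(n):
            p = np.linspace(0, 1, n)
            return np.column_stack([np.sin(2 * np.pi * p), np.cos(np.pi * p), p**2])
        a, b = make(120), make(240)
        out_a = normalize_cycles(a, [0, 119])
        out_b = normalize_cycles(b, [0, 239])
        assert np.abs(out_a - out_b).max() < 1e-6

    def test_endpoints_preserved_exactly(self):
        rng = np.random.default_rng(2)
        angles = rng.normal(size=(50, 3))
        out = normalize_cycles(angles, [0, 49])
        assert np.allclose(out[0, 0], angles[0], atol=1e-14)
        assert np.allclose(out[0, -1], angles[49], atol=1e-14)

    def test_short_cycle_rejected(self):
        with pytest.raises(CycleError, match=">= 4"):
            normalize_cycles(np.zeros((10, 3)), [0, 2])


def _periodic_cycles(n_cycles=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    p = np.linspace(0, 1, N_PHASE_POINTS)
    base = np.column_stack([
        10 * np.sin(2 * np.pi * p), 4 * np.cos(2 * np.pi * p), 3 * np.sin(4 * np.pi * p)
    ])
    cycles = np.repeat(base[None], n_cycles, axis=0)
    if noise:
        cycles = cycles + rng.normal(0, noise, cycles.shape)
    return cycles


class TestAlignCycles:
    def test_identical_cycles_zero_shift(self):
        aligned, shifts = align_cycles(_periodic_cycles())
        assert np.array_equal(shifts, np.zeros(6, dtype=int))
        assert np.array_equal(aligned, _periodic_cycles())

    def test_preshifted_cycle_recovered(self):
        cycles = _periodic_cycles()
        body = np.roll(cycles[2, :-1], 3, axis=0)
        cycles[2] = np.concatenate([body, body[:1]], axis=0)
        aligned, shifts = align_cycles(cycles)
        assert shifts[2] == -3
        assert mean_sd(aligned)[0] < 1e-9

    def test_shift_clamped_to_bound(self):
        cycles = _periodic_cycles()
        body = np.roll(cycles[2, :-1], 15, axis=0)
        cycles[2] = np.concatenate([body, body[:1]], axis=0)
        _, shifts = align_cycles(cycles, max_shift=10)
        assert abs(shifts[2]) <= 10

    def test_alignment_never_increases_meansd_fe(self):
        for seed in range(5):
            cycles = _periodic_cycles(n_cycles=10, seed=seed, noise=0.8)
            aligned, _ = align_cycles(cycles)
            assert mean_sd(aligned)[0] <= mean_sd(cycles)[0] + 1e-12

    def test_needs_two_cycles(self):
        with pytest.raises(CycleError):
            align_cycles(_periodic_cycles()[:1])


class TestMeanSd:
    def test_identical_cycles_zero(self):
        assert np.allclose(mean_sd(_periodic_cycles()), 0.0)

    def test_constant_offset_closed_form(self):
        cycles = _periodic_cycles(n_cycles=2)
        cycles[1, :, 0] += 1.0
        ms = mean_sd(cycles)
        # SD of {a, a+1} with n-1 denominator is 1/sqrt(2) at every phase point
        assert ms[0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
        assert ms[1] == 0.0 and ms[2] == 0.0

    def test_scales_linearly_about_mean(self):
        cycles = _periodic_cycles(n_cycles=8, noise=0.5)
        m = cycles.mean(axis=0, keepdims=True)
        scaled = m + 3.0 * (cycles - m)
        assert np.allclose(mean_sd(scaled), 3.0 * mean_sd(cycles), atol=1e-9)

    def test_offset_invariance(self):
        cycles = _periodic_cycles(n_cycles=8, noise=0.5)
        assert np.allclose(mean_sd(cycles + 5.0), mean_sd(cycles), atol=1e-9)


class TestAmplitudeVelocity:
    def test_raised_cosine_amplitude(self, noiseless_trial):
        series, _ = noiseless_trial
        peaks = detect_cycles(series.flexion_extension)
        sel = select_analysis_cycles(peaks, 40)
        amp = amplitude(normalize_cycles(series.angles, sel))
        assert amp[0] == pytest.approx(20.0, abs=0.01)

    def test_constant_signal_zero(self):
        assert np.allclose(amplitude(np.ones((3, N_PHASE_POINTS, 3))), 0.0)

    def test_mean_extrema_arithmetic(self):
        cycles = np.zeros((2, N_PHASE_POINTS, 3))
        cycles[0, :, 0], cycles[1, :, 0] = 1.0, -1.0   # per-cycle minima {1, -1}
        cycles[0, 50, 0], cycles[1, 50, 0] = 21.0, 19.0  # per-cycle maxima {21, 19}
        assert amplitude(cycles)[0] == pytest.approx(20.0)

    def test_velocity_arithmetic(self):
        assert velocity(45, 150.0) == pytest.approx(0.30)
        assert velocity(40, 105.3) == pytest.approx(0.3799, abs=1e-4)

    def test_velocity_rejects_nonpositive_duration(self):
        with pytest.raises(CycleError):
            velocity(40, 0.0)
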