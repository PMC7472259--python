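import numpy as np
import pytest

from pulsefusion.errors import ConfigurationError, SegmentError
from pulsefusion.features import (
    HarmonicFeatures,
    compute_base_frequency,
    compute_harmonics,
    compute_segment_features,
    compute_time_features,
    estimate_heart_rate,
    triangle_angle,
)
from pulsefusion.fiducials import BeatFiducials, FiducialPoint
from pulsefusion.preprocess import PPGRecording, segment_sliding_windows
from pulsefusion.synth import PPGSimConfig, simulate_ppg

FS = 25.0


def _point(time: float, amplitude: float) -> FiducialPoint:
    return FiducialPoint(index=int(round(time * FS)), time=time, amplitude=amplitude)


@pytest.fixture
def hand_beat() -> BeatFiducials:
    """Hand-constructed fiducials with easily verified arithmetic."""
    return BeatFiducials(
        pwb=_point(1.00, 0.0),
        pwsp=_point(1.20, 1.0),
        pwdp=_point(1.50, 0.4),
        pwe=_point(2.00, 0.0),
        next_pwsp_time=2.20,
    )


class TestTriangleAngle:
    def test_pythagorean_triple_gives_right_angle(self):
        assert triangle_angle(3.0, 4.0, 5.0) == pytest.approx(90.0)

    def test_collinear_points_give_straight_angle(self):
        # peak exactly on the line through its neighbours: a + b = c
        assert triangle_angle(1.0, 1.0, 2.0) == pytest.approx(180.0)

    def test_degenerate_side_rejected(self):
        with pytest.raises(ConfigurationError):
            triangle_angle(0.0, 1.0, 1.0)


class TestTimeFeatures:
    def test_hand_constructed_beat_arithmetic(self, hand_beat):
        feats = compute_time_features([hand_beat])
        assert feats.f1 == pytest.approx(np.hypot(0.30, 0.60), abs=1e-12)
        assert feats.f2 == pytest.approx(np.hypot(0.50, 0.40), abs=1e-12)
        assert feats.f4 == pytest.approx(np.hypot(0.20, 1.0), abs=1e-12)
        assert feats.f5 == pytest.approx(0.20)
        assert feats.f6 == pytest.approx(0.80)
        assert feats.f7 == pytest.approx(0.30)
        assert feats.f8 == pytest.approx(1.00)
        assert np.isnan(feats.f3)  # no waveform supplied

    def test_beat_without_diastolic_peak_skips_f1_f2_f7(self, hand_beat):
        from dataclasses import replace

        beats = [hand_beat, replace(hand_beat, pwdp=None)]
        feats = compute_time_features(beats)
        # f1/f2/f7 averages use only the beat with a PWDP
        assert feats.f1 == pytest.approx(np.hypot(0.30, 0.60))
        assert feats.f7 == pytest.approx(0.30)
        # f4-f6, f8 average over both
        assert feats.f5 == pytest.approx(0.20)

    def test_no_beats_rejected(self):
        with pytest.raises(SegmentError):
            compute_time_features([])


class TestHeartRateAndBase:
    @pytest.mark.parametrize("bpm,f0", [(96.0, 1.6), (60.0, 1.0), (72.0, 1.2)])
    def test_base_frequency(self, bpm, f0):
        assert compute_base_frequency(bpm) == pytest.approx(f0)

    def test_base_frequency_rejects_nonpositive(self):
        with pytest.raises(ConfigurationError):
            compute_base_frequency(0.0)

    @pytest.mark.parametrize(
        "times,bpm",
        [
            (np.arange(10.0), 60.0),
            (np.arange(16) * 0.625, 96.0),
            (np.cumsum([0.0, 0.9, 1.0, 1.1]), 60.0),  # median interval 1.0 s
        ],
    )
    def test_heart_rate_from_peak_times(self, times, bpm):
        assert estimate_heart_rate(times) == pytest.approx(bpm)

    def test_single_peak_rejected(self):
        with pytest.raises(SegmentError):
            estimate_heart_rate([1.0])


class TestHarmonics:
    def test_exact_bin_tone_reads_unit_amplitude(self):
        t = np.arange(250) / FS
        x = np.cos(2 * np.pi * 1.6 * t)
        h = compute_harmonics(x, FS, base_frequency=1.6)
        assert h.amplitudes[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(h.amplitudes[1:] < 1e-10)

    def test_two_tone_superposition(self):
        t = np.arange(250) / FS
        x = np.cos(2 * np.pi * 1.6 * t) + 0.3 * np.cos(2 * np.pi * 3.2 * t)
        h = compute_harmonics(x, FS, base_frequency=1.6)
        assert h.amplitudes[0] == pytest.approx(1.0, abs=1e-9)
        assert h.amplitudes[1] == pytest.approx(0.3, abs=1e-9)

    def test_beat_train_matches_sinusoid_regression_oracle(self):
        """Nearest-bin FFT amplitudes agree with a brute-force least-squares
        fit of sinusoids at n x 1.6 Hz on a clean 96-bpm beat train."""
        config = PPGSimConfig(
            duration=10.0, heart_rate=96.0, diastolic_ratio=0.3,
            systolic_diastolic_delay=0.25, systolic_width=0.07, diastolic_width=0.07,
        )
        x = simulate_ppg(config).samples
        x = x - x.mean()
        h = compute_harmonics(x, FS, base_frequency=1.6, n_harmonics=7)
        t = np.arange(x.size) / FS
        design = [np.ones_like(t)]
        for n in range(1, 8):
            design += [np.cos(2 * np.pi * n * 1.6 * t), np.sin(2 * np.pi * n * 1.6 * t)]
        coef, *_ = np.linalg.lstsq(np.column_stack(design), x, rcond=None)
        oracle = np.hypot(coef[1::2], coef[2::2])
        np.testing.assert_allclose(h.amplitudes, oracle, rtol=0.02)

    def test_harmonics_beyond_nyquist_are_zero(self):
        t = np.arange(250) / FS
        x = np.cos(2 * np.pi * 1.6 * t)
        h = compute_harmonics(x, FS, base_frequency=1.6, n_harmonics=10)
        assert h.amplitudes[8] == 0.0  # 14.4 Hz > 12.5 Hz Nyquist
        assert h.amplitudes[9] == 0.0

    def test_wrong_segment_length_rejected(self):
        x = np.zeros(100)
        with pytest.raises(SegmentError):
            compute_harmonics(x, FS, 1.0, expected_duration=10.0)

    def test_amplitude_scale_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(250)
        h1 = compute_harmonics(x, FS, 1.2)
        h2 = compute_harmonics(3.5 * x, FS, 1.2)
        np.testing.assert_allclose(h2.amplitudes, 3.5 * h1.amplitudes, rtol=1e-12)

    def test_circular_shift_by_whole_beats_leaves_amplitudes(self):
        config = PPGSimConfig(duration=10.0, heart_rate=60.0, systolic_width=0.08,
                              diastolic_ratio=0.3, systolic_diastolic_delay=0.3)
        x = simulate_ppg(config).samples
        h1 = compute_harmonics(x, FS, 1.0)
        h2 = compute_harmonics(np.roll(x, 25), FS, 1.0)  # one full beat
        np.testing.assert_allclose(h1.amplitudes, h2.amplitudes, atol=1e-6)

    def test_parseval_bound(self):
        config = PPGSimConfig(duration=10.0, heart_rate=72.0)
        x = simulate_ppg(config).samples
        x = x - x.mean()
        h = compute_harmonics(x, FS, 1.2)
        assert np.sum(h.amplitudes**2) <= 2.0 * np.mean(x**2) + 1e-12

    def test_negative_amplitudes_rejected_by_container(self):
        with pytest.raises(ConfigurationError):
            HarmonicFeatures(base_frequency=1.0, amplitudes=-np.ones(10))


class TestSegmentFeatures:
    def test_clean_60bpm_segment(self, clean_60bpm_recording):
        segments = segment_sliding_windows(clean_60bpm_recording, 10.0, 1.0)
        feats = compute_segment_features(segments[0], window_duration=10.0)
        assert feats is not None
        assert feats.time.f8 == pytest.approx(1.0, abs=0.04)
        assert feats.harmonic.base_frequency == pytest.approx(1.0, abs=0.02)
        assert feats.n_beats_used >= 8

    def test_f5_plus_f6_approximates_f8(self, clean_60bpm_recording):
        segments = segment_sliding_windows(clean_60bpm_recording, 10.0, 1.0)
        feats = compute_segment_features(segments[0])
        assert feats.time.f5 + feats.time.f6 == pytest.approx(feats.time.f8, abs=0.05)

    def test_all_zero_segment_invalid(self):
        rec = PPGRecording(samples=np.zeros(250), sampling_rate=FS)
        assert compute_segment_features(rec) is None

    def test_locality_segment_equals_standalone_slice(self, clean_60bpm_recording):
        segments = segment_sliding_windows(clean_60bpm_recording, 10.0, 1.0)
        seg = segments[7]
        standalone = PPGRecording(samples=seg.samples.copy(), sampling_rate=FS)
        a = compute_segment_features(seg)
        b = compute_segment_features(standalone)
        np.testing.assert_allclose(a.as_array(), b.as_array(), atol=1e-12)

    def test_gain_invariance_of_all_features(self, clean_60bpm_recording):
        """Min-max normalization makes every extracted feature invariant to
        the device gain."""
        seg = segment_sliding_windows(clean_60bpm_recording, 10.0, 1.0)[0]
        scaled = PPGRecording(samples=7.3 * seg.samples, sampling_rate=FS)
        a = compute_segment_features(seg)
        b = compute_segment_features(scaled)
        np.testing.assert_allclose(a.as_array(), b.as_array(), atol=1e-12)
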