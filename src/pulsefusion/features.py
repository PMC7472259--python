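"""Per-segment PPG features: 8 time-domain + 10 harmonic amplitudes.

Time-domain features (beat-averaged over a segment; amplitudes are
per-segment min-max normalized to [0, 1] before any distance is taken so
the features are device-gain invariant and time/amplitude are
commensurable):

======  ==========================================================  =======
f1      2-D distance PWSP-PWDP in the (time, amplitude) plane       norm.
f2      2-D distance PWDP-PWE                                       norm.
f3      angle at the systolic peak of the triangle through its       deg
        immediately adjacent samples (time in sample units)
f4      2-D distance PWSP-PWB (pulse-wave amplitude proxy)          norm.
f5      systolic phase duration, PWSP - PWB                          s
f6      diastolic phase duration, PWE - PWSP                         s
f7      systolic-to-diastolic propagation time, PWDP - PWSP          s
f8      inter-beat interval, next PWSP - PWSP                        s
======  ==========================================================  =======

Harmonic features C1..C10 are the FFT amplitude-spectrum values at the
bins nearest n x f0, where the base frequency f0 = heart rate / 60 (a
96-bpm heart rate puts C1 at 1.6 Hz, C2 at 3.2 Hz). The spectrum is
normalized so a unit-amplitude sinusoid on an exact bin reads 1.0
(2|X_k|/N for k > 0). C0 — interpreted in pulse resonance theory as the
heart's total load — is not extracted. Harmonics at or above Nyquist are
reported as 0 with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SegmentError
from .fiducials import (
    BeatFiducials,
    DetectorConfig,
    assemble_beats,
    detect_diastolic_peaks,
    detect_pulse_begin,
    detect_systolic_peaks,
)
from .preprocess import (
    PPGRecording,
    Segment,
    bandpass_filter,
    pmaf_denoise,
    segment_sliding_windows,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TimeDomainFeatures",
    "HarmonicFeatures",
    "SegmentFeatures",
    "TIME_FEATURE_NAMES",
    "HARMONIC_FEATURE_NAMES",
    "PPG_FEATURE_NAMES",
    "triangle_angle",
    "compute_time_features",
    "compute_base_frequency",
    "estimate_heart_rate",
    "compute_harmonics",
    "compute_segment_features",
    "extract_recording_features",
]

TIME_FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 9))
HARMONIC_FEATURE_NAMES = tuple(f"c{i}" for i in range(1, 11))
PPG_FEATURE_NAMES = TIME_FEATURE_NAMES + HARMONIC_FEATURE_NAMES


@dataclass(frozen=True)
class TimeDomainFeatures:
    """Beat-averaged time-domain features. f1/f2/f7 (and f3 by convention)
    use only beats with a diastolic peak; they are NaN when no beat in the
    segment has one."""

    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float
    f8: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TIME_FEATURE_NAMES])


@dataclass(frozen=True)
class HarmonicFeatures:
    """Amplitudes at the first ten harmonics of the base frequency."""

    base_frequency: float
    amplitudes: np.ndarray  # shape (10,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if self.base_frequency <= 0:
            raise ConfigurationError("base_frequency must be positive")
        if np.any(self.amplitudes < 0):
            raise ConfigurationError("harmonic amplitudes are non-negative")

    def as_array(self) -> np.ndarray:
        return self.amplitudes


@dataclass(frozen=True)
class SegmentFeatures:
    """The 18 PPG features of one segment plus bookkeeping."""

    time: TimeDomainFeatures
    harmonic: HarmonicFeatures
    n_beats_used: int

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.time.as_array(), self.harmonic.as_array()])


def triangle_angle(a: float, b: float, c: float) -> float:
    """Angle (degrees) at the vertex C opposite side c, by the law of
    cosines: arccos((a^2 + b^2 - c^2) / 2ab)."""
    if a <= 0 or b <= 0:
        raise ConfigurationError("triangle sides a and b must be positive")
    cosine = np.clip((a * a + b * b - c * c) / (2 * a * b), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def _peak_angle(samples: np.ndarray, index: int) -> float | None:
    """f3: angle at the peak sample between its two neighbours, with the
    abscissa in sample units on the normalized waveform."""
    if index < 1 or index > samples.size - 2:
        return None
    dy_prev = samples[index] - samples[index - 1]
    dy_next = samples[index + 1] - samples[index]
    a = math.hypot(1.0, dy_prev)
    b = math.hypot(1.0, dy_next)
    c = math.hypot(2.0, samples[index + 1] - samples[index - 1])
    return triangle_angle(a, b, c)


def compute_time_features(
    beats: list[BeatFiducials],
    samples: np.ndarray | None = None,
) -> TimeDomainFeatures:
    """Average the per-beat time-domain features over a segment's beats.

    ``samples`` (the normalized segment waveform) is required for f3; when
    omitted f3 is NaN. Fiducial amplitudes are used as stored, so they must
    already be on the normalized scale.
    """
    if not beats:
        raise SegmentError("at least one complete beat is required")

    def dist(p, q) -> float:
        return math.hypot(p.time - q.time, p.amplitude - q.amplitude)

    f1s, f2s, f3s, f4s, f5s, f6s, f7s, f8s = ([] for _ in range(8))
    for beat in beats:
        f4s.append(dist(beat.pwsp, beat.pwb))
        f5s.append(beat.pwsp.time - beat.pwb.time)
        f6s.append(beat.pwe.time - beat.pwsp.time)
        if beat.next_pwsp_time is not None:
            f8s.append(beat.next_pwsp_time - beat.pwsp.time)
        if beat.pwdp is not None:
            f1s.append(dist(beat.pwsp, beat.pwdp))
            f2s.append(dist(beat.pwdp, beat.pwe))
            f7s.append(beat.pwdp.time - beat.pwsp.time)
            if samples is not None:
                angle = _peak_angle(np.asarray(samples, dtype=float), beat.pwsp.index)
                if angle is not None:
                    f3s.append(angle)

    def mean(values: list[float]) -> float:
        return float(np.mean(values)) if values else float("nan")

    return TimeDomainFeatures(
        f1=mean(f1s), f2=mean(f2s), f3=mean(f3s), f4=mean(f4s),
        f5=mean(f5s), f6=mean(f6s), f7=mean(f7s), f8=mean(f8s),
    )


def compute_base_frequency(heart_rate: float) -> float:
    """Base frequency f0 = heart rate / 60 (96 bpm -> 1.6 Hz)."""
    if heart_rate <= 0:
        raise ConfigurationError("heart_rate must be positive")
    return heart_rate / 60.0


def estimate_heart_rate(pwsp_times: np.ndarray | list[float]) -> float:
    """Heart rate (bpm) as 60 / median inter-peak interval; robust to a
    single mis-detected beat."""
    times = np.asarray(pwsp_times, dtype=float)
    if times.size < 2:
        raise SegmentError("need at least 2 systolic peaks to estimate heart rate")
    ibi = float(np.median(np.diff(times)))
    if ibi <= 0:
        raise SegmentError("systolic peak times must be strictly increasing")
    return 60.0 / ibi


def compute_harmonics(
    samples: np.ndarray,
    sampling_rate: float,
    base_frequency: float,
    n_harmonics: int = 10,
    expected_duration: float | None = None,
    taper: str = "rect",
) -> HarmonicFeatures:
    """Amplitudes at the bins nearest n x f0, n = 1..n_harmonics.

    The segment mean is removed, the amplitude spectrum 2|X_k|/N computed
    (unit-amplitude exact-bin sinusoid -> 1.0), and the nearest bin taken
    per harmonic (no interpolation; a 10-s window gives 0.1-Hz bins).
    ``taper='hann'`` applies a Hann window with coherent-gain correction.
    """
    x = np.asarray(samples, dtype=float)
    fs = sampling_rate
    if base_frequency <= 0:
        raise ConfigurationError("base_frequency must be positive")
    if expected_duration is not None and x.size != int(round(expected_duration * fs)):
        raise SegmentError(
            f"segment has {x.size} samples, expected {int(round(expected_duration * fs))}"
        )
    n = x.size
    x = x - x.mean()
    if taper == "hann":
        w = np.hanning(n)
        x = x * w / w.mean()
    elif taper != "rect":
        raise ConfigurationError(f"unknown taper {taper!r}")
    spectrum = 2.0 * np.abs(np.fft.rfft(x)) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amplitudes = np.zeros(n_harmonics)
    for h in range(1, n_harmonics + 1):
        target = h * base_frequency
        if target >= fs / 2:
            logger.debug("harmonic %d at %.2f Hz exceeds Nyquist; reported as 0", h, target)
            continue
        amplitudes[h - 1] = spectrum[int(np.argmin(np.abs(freqs - target)))]
    return HarmonicFeatures(base_frequency=base_frequency, amplitudes=amplitudes)


def compute_segment_features(
    segment: Segment | PPGRecording,
    detector_config: DetectorConfig | None = None,
    window_duration: float | None = None,
    taper: str = "rect",
) -> SegmentFeatures | None:
    """All 18 PPG features of one (already denoised) segment.

    Pipeline: min-max normalize the waveform -> delineate fiducials ->
    beat-average the time-domain features -> estimate the heart rate from
    the systolic peaks -> extract harmonics of the base frequency from the
    normalized waveform. Returns None for invalid segments (flat signal,
    fewer than 2 systolic peaks, or no complete beat).
    """
    detector_config = detector_config or DetectorConfig()
    x, fs, t0 = segment.samples, segment.sampling_rate, segment.start_time
    span = float(np.ptp(x))
    if span == 0:
        logger.info("segment at t=%.1f s is flat: invalid", t0)
        return None
    xn = (x - x.min()) / span

    pwsps = detect_systolic_peaks(segment, detector_config)
    if len(pwsps) < 2:
        logger.info("segment at t=%.1f s: %d systolic peaks: invalid", t0, len(pwsps))
        return None
    pwbs = detect_pulse_begin(segment, pwsps, detector_config)
    if len(pwbs) != len(pwsps):
        pwsps = [p for p in pwsps if any(b.index < p.index for b in pwbs)][: len(pwbs)]
    pwdps = detect_diastolic_peaks(segment, pwsps, detector_config)
    beats = assemble_beats(pwbs, pwsps, pwdps)
    if not beats:
        logger.info("segment at t=%.1f s: no complete beat: invalid", t0)
        return None

    def normalized(p):
        return type(p)(index=p.index, time=p.time, amplitude=float(xn[p.index]))

    norm_beats = [
        BeatFiducials(
            pwb=normalized(b.pwb),
            pwsp=normalized(b.pwsp),
            pwe=normalized(b.pwe),
            pwdp=normalized(b.pwdp) if b.pwdp is not None else None,
            next_pwsp_time=b.next_pwsp_time,
        )
        for b in beats
    ]
    time_features = compute_time_features(norm_beats, samples=xn)
    heart_rate = estimate_heart_rate([p.time for p in pwsps])
    f0 = compute_base_frequency(heart_rate)
    harmonic = compute_harmonics(
        xn, fs, f0, expected_duration=window_duration, taper=taper
    )
    return SegmentFeatures(time=time_features, harmonic=harmonic, n_beats_used=len(beats))


def extract_recording_features(
    recording: PPGRecording,
    window: float = 10.0,
    hop: float = 1.0,
    detector_config: DetectorConfig | None = None,
    band: tuple[float, float] = (0.5, 8.0),
    use_pmaf: bool = True,
    pmaf_k: int = 3,
) -> pd.DataFrame:
    """Denoise a recording and compute the 18 PPG features per sliding
    window.

    Returns a DataFrame with one row per *valid* segment (columns:
    subject_id, segment_index, f1..f8, c1..c10, n_beats_used); rows whose
    time-domain features contain NaN (no diastolic peak found anywhere in
    the segment) are excluded and logged.
    """
    filtered = bandpass_filter(recording, *band)
    if use_pmaf:
        filtered = pmaf_denoise(filtered, k=pmaf_k)
    segments = segment_sliding_windows(filtered, window=window, hop=hop)
    rows = []
    n_invalid = 0
    for i, seg in enumerate(segments):
        feats = compute_segment_features(seg, detector_config, window_duration=window)
        if feats is None or not np.all(np.isfinite(feats.as_array())):
            n_invalid += 1
            continue
        row = {"subject_id": recording.subject_id, "segment_index": i,
               "n_beats_used": feats.n_beats_used}
        row.update(dict(zip(PPG_FEATURE_NAMES, feats.as_array())))
        rows.append(row)
    if n_invalid:
        logger.info(
            "%s: %d of %d segments invalid", recording.subject_id, n_invalid, len(segments)
        )
    columns = ["subject_id", "segment_index", *PPG_FEATURE_NAMES, "n_beats_used"]
    return pd.DataFrame(rows, columns=columns)
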