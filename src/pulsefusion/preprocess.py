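"""PPG recording container, denoising and sliding-window segmentation.

The preprocessing chain applied before feature extraction is

1. zero-phase Butterworth bandpass (default 0.5-8 Hz) to remove baseline
   wander and out-of-band noise without shifting fiducial timings;
2. a periodic moving-average filter (PMAF) that exploits the
   quasi-periodicity of the pulse waveform: the signal is cut into beat
   periods, each period is resampled onto a common phase grid, every
   phase-aligned sample is replaced by the average over the K surrounding
   periods, and the result is resampled back onto the original time grid;
3. segmentation into fixed-length sliding windows (default 10 s window,
   1 s hop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, SegmentError

logger = logging.getLogger(__name__)

__all__ = [
    "PPGRecording",
    "Segment",
    "bandpass_filter",
    "estimate_beat_period",
    "pmaf_denoise",
    "segment_sliding_windows",
]


@dataclass(frozen=True)
class PPGRecording:
    """A uniformly sampled pulse waveform.

    Parameters
    ----------
    samples : ndarray
        Signal values, arbitrary units.
    sampling_rate : float
        Samples per second (Hz).
    start_time : float
        Time of the first sample, seconds.
    subject_id : str, optional
        Identifier carried through exports.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    subject_id: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ConfigurationError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ConfigurationError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds (n / fs)."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "PPGRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class Segment:
    """A half-open sample-index window [start_index, end_index) of a recording."""

    recording: PPGRecording = field(repr=False)
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        n = self.recording.n_samples
        if not (0 <= self.start_index < self.end_index <= n):
            raise ConfigurationError(
                f"segment [{self.start_index}, {self.end_index}) outside recording of {n} samples"
            )

    @property
    def samples(self) -> np.ndarray:
        return self.recording.samples[self.start_index : self.end_index]

    @property
    def sampling_rate(self) -> float:
        return self.recording.sampling_rate

    @property
    def start_time(self) -> float:
        return self.recording.start_time + self.start_index / self.recording.sampling_rate

    @property
    def duration(self) -> float:
        return (self.end_index - self.start_index) / self.recording.sampling_rate


def bandpass_filter(
    recording: PPGRecording,
    low: float = 0.5,
    high: float = 8.0,
    order: int = 4,
) -> PPGRecording:
    """Zero-phase Butterworth bandpass.

    Forward-backward filtering (``filtfilt``) is used so that fiducial
    timings are not shifted by the filter's phase response; the effective
    attenuation is that of the squared magnitude response.
    """
    nyq = recording.sampling_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ConfigurationError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples)
    return recording.with_samples(filtered)


def estimate_beat_period(
    recording: PPGRecording,
    min_period: float = 60.0 / 200.0,
    max_period: float = 60.0 / 35.0,
) -> float:
    """Beat period (s) from the first autocorrelation peak in a plausible
    heart-rate range (35-200 bpm by default)."""
    x = recording.samples - recording.samples.mean()
    fs = recording.sampling_rate
    n = x.size
    acf = sps.correlate(x, x, mode="full")[n - 1 :]
    lo = max(1, int(round(min_period * fs)))
    hi = min(n - 1, int(round(max_period * fs)))
    if hi <= lo:
        raise SegmentError("recording too short to estimate a beat period")
    window = acf[lo : hi + 1]
    peaks, _ = sps.find_peaks(window)
    lag = lo + (int(peaks[np.argmax(window[peaks])]) if peaks.size else int(np.argmax(window)))
    return lag / fs


def pmaf_denoise(
    recording: PPGRecording,
    beat_period: float | None = None,
    k: int = 3,
    anchors: np.ndarray | None = None,
) -> PPGRecording:
    """Periodic moving-average filter.

    The recording is anchored at detected beat maxima, each inter-anchor
    period is linearly resampled to a common length, phase-aligned samples
    are averaged over a centred window of ``k`` periods (truncated at the
    ends), and each averaged period is resampled back onto its original
    sample grid. Samples before the first anchor and after the last are
    passed through unchanged, so the output length equals the input length.

    For an exactly periodic signal whose period is an integer number of
    samples the filter is the identity.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    fs = recording.sampling_rate
    if beat_period is None:
        beat_period = estimate_beat_period(recording)
    if beat_period <= 0:
        raise ConfigurationError("beat_period must be positive")
    if recording.duration < 3 * beat_period:
        raise SegmentError(
            "recording must cover at least 3 beat periods; use a longer input or smaller period"
        )

    x = recording.samples
    if anchors is None:
        # Anchor on local maxima spaced at least ~0.6 periods apart. Anchors
        # are located on a lightly smoothed copy so sample-level noise does
        # not jitter the phase alignment; the smoothing never touches the
        # output. Callers with known beat positions may pass them instead.
        min_dist = max(1, int(round(0.6 * beat_period * fs)))
        smooth_n = max(1, int(round(0.12 * beat_period * fs)))
        anchor_src = (
            np.convolve(x, np.ones(smooth_n) / smooth_n, mode="same") if smooth_n > 1 else x
        )
        anchors, _ = sps.find_peaks(anchor_src, distance=min_dist)
    else:
        anchors = np.asarray(anchors, dtype=int)
    if anchors.size < k + 1:
        raise SegmentError(
            f"found {anchors.size} beat anchors; need at least k+1={k + 1} "
            "(shorten k or provide a longer input)"
        )

    n_periods = anchors.size - 1
    phase_len = max(4, int(round(beat_period * fs)))
    grid = np.arange(phase_len) / phase_len  # common phase grid in [0, 1)

    aligned = np.empty((n_periods, phase_len))
    for i in range(n_periods):
        a, b = anchors[i], anchors[i + 1]
        idx = np.arange(a, b + 1)
        phase = (idx - a) / (b - a)
        aligned[i] = np.interp(grid, phase, x[idx])

    # Truncated centred moving average across periods (cumsum trick).
    h = (k - 1) // 2
    hi_h = k - 1 - h
    csum = np.vstack([np.zeros(phase_len), np.cumsum(aligned, axis=0)])
    out = np.array(x, copy=True)
    for i in range(n_periods):
        lo = max(0, i - h)
        hi = min(n_periods, i + hi_h + 1)
        mean_period = (csum[hi] - csum[lo]) / (hi - lo)
        a, b = anchors[i], anchors[i + 1]
        idx = np.arange(a, b)
        phase = (idx - a) / (b - a)
        # append the period start value at phase 1.0 for interpolation continuity
        out[a:b] = np.interp(phase, np.append(grid, 1.0), np.append(mean_period, mean_period[0]))
    return recording.with_samples(out)


def segment_sliding_windows(
    recording: PPGRecording,
    window: float = 10.0,
    hop: float = 1.0,
) -> list[Segment]:
    """Cut a recording into sliding windows starting at t = 0, hop, 2*hop, ...

    The number of windows follows the convention
    ``count = floor((duration - window) / hop)`` — a 300-s recording with a
    10-s window and 1-s hop yields 290 segments.
    """
    if window <= 0 or hop <= 0:
        raise ConfigurationError("window and hop must be positive")
    fs = recording.sampling_rate
    win_n = int(round(window * fs))
    hop_n = int(round(hop * fs))
    if win_n < 2:
        raise ConfigurationError("window too short for the sampling rate")
    duration = recording.duration
    if duration < window:
        logger.warning(
            "recording of %.1f s shorter than window %.1f s: no segments", duration, window
        )
        return []
    count = int(np.floor((duration - window) / hop))
    segments = []
    for i in range(count):
        start = i * hop_n
        segments.append(Segment(recording, start, start + win_n))
    return segments
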