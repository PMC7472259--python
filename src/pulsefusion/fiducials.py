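"""Per-beat fiducial delineation on a PPG segment.

Four fiducial points are located on each beat:

* **PWSP** — pulse wave systolic peak. Detected with an event-related
  moving-average scheme: the (bandpass-filtered) signal is clipped at zero
  and squared; a short "peak-scale" and a long "beat-scale" moving average
  are compared; runs where the short average exceeds the long average plus
  a small offset form blocks of interest; blocks shorter than the
  peak-scale window are rejected and the systolic peak is the argmax of the
  original signal within each surviving block.
* **PWB** — pulse wave begin (onset). The same block detector run on the
  negated signal, so onsets become maxima; each candidate is paired with
  the nearest following systolic peak, with the inter-beat minimum as a
  fallback.
* **PWDP** — diastolic peak. The smoothed second-order finite difference
  is inverted; the first sufficiently prominent local maximum after the
  systolic peak and before the beat's trough marks the diastolic bump.
  Beats without one record the point as absent.
* **PWE** — pulse wave end, defined as the next beat's PWB so that the
  beat partition is exhaustive; the final beat (no successor) is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import SegmentError
from .preprocess import Segment

logger = logging.getLogger(__name__)

__all__ = [
    "FiducialPoint",
    "BeatFiducials",
    "DetectorConfig",
    "detect_systolic_peaks",
    "detect_pulse_begin",
    "detect_diastolic_peaks",
    "assemble_beats",
    "delineate",
]


@dataclass(frozen=True)
class FiducialPoint:
    """A (sample index, time, amplitude) landmark within a segment."""

    index: int
    time: float
    amplitude: float


@dataclass(frozen=True)
class BeatFiducials:
    """One beat's landmarks. ``pwdp`` is None when no diastolic bump was
    found; ``next_pwsp_time`` (the following beat's systolic peak) feeds the
    inter-beat-interval feature."""

    pwb: FiducialPoint
    pwsp: FiducialPoint
    pwe: FiducialPoint
    pwdp: FiducialPoint | None = None
    next_pwsp_time: float | None = None


@dataclass(frozen=True)
class DetectorConfig:
    """Delineator constants (defaults are the standard event-related
    moving-average values: 111 ms peak window, 667 ms beat window, 2%
    offset)."""

    ma_peak_window: float = 0.111
    ma_beat_window: float = 0.667
    threshold_offset_fraction: float = 0.02
    second_derivative_smoothing_window: float = 0.120
    diastolic_prominence_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.ma_peak_window < self.ma_beat_window):
            raise SegmentError("need 0 < ma_peak_window < ma_beat_window")
        if self.second_derivative_smoothing_window <= 0:
            raise SegmentError("second_derivative_smoothing_window must be positive")


def _as_array(segment) -> tuple[np.ndarray, float, float]:
    if isinstance(segment, Segment):
        return segment.samples, segment.sampling_rate, segment.start_time
    return np.asarray(segment.samples, dtype=float), segment.sampling_rate, getattr(
        segment, "start_time", 0.0
    )


def _window_samples(seconds: float, fs: float) -> int:
    return max(1, int(round(seconds * fs)))


def _detect_blocks(x: np.ndarray, fs: float, config: DetectorConfig) -> list[tuple[int, int]]:
    """Blocks of interest (half-open index runs) from the two-moving-average
    comparison on the clipped, squared signal."""
    w_peak = _window_samples(config.ma_peak_window, fs)
    w_beat = _window_samples(config.ma_beat_window, fs)
    if x.size < w_beat:
        raise SegmentError(
            f"segment of {x.size} samples shorter than beat-scale window ({w_beat} samples)"
        )
    y = np.square(np.clip(x, 0.0, None))
    if not np.any(y > 0):
        return []
    ma_peak = uniform_filter1d(y, w_peak, mode="nearest")
    ma_beat = uniform_filter1d(y, w_beat, mode="nearest")
    threshold = ma_beat + config.threshold_offset_fraction * float(y.mean())
    mask = ma_peak > threshold
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    blocks = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo >= w_peak:
            blocks.append((int(lo), int(hi)))
    return blocks


def detect_systolic_peaks(segment, config: DetectorConfig | None = None) -> list[FiducialPoint]:
    """Systolic peaks in time order (strictly increasing indices)."""
    config = config or DetectorConfig()
    x, fs, t0 = _as_array(segment)
    points = []
    for lo, hi in _detect_blocks(x, fs, config):
        idx = lo + int(np.argmax(x[lo:hi]))  # argmax ties break earliest
        points.append(FiducialPoint(index=idx, time=t0 + idx / fs, amplitude=float(x[idx])))
    return points


def detect_pulse_begin(
    segment,
    systolic_peaks: list[FiducialPoint],
    config: DetectorConfig | None = None,
) -> list[FiducialPoint]:
    """One pulse onset (PWB) per systolic peak, strictly before it.

    Onsets are the block-detector maxima of the negated signal; each is
    paired with the nearest following systolic peak. Peaks without a paired
    candidate fall back to the signal minimum between consecutive peaks;
    a peak at the very first sample cannot have an onset and is dropped.
    """
    config = config or DetectorConfig()
    x, fs, t0 = _as_array(segment)
    if not systolic_peaks:
        return []
    candidates = [p.index for p in detect_systolic_peaks_on(-x, fs, t0, config)]
    peak_idx = [p.index for p in systolic_peaks]
    onsets: list[FiducialPoint] = []
    cand = np.asarray(candidates, dtype=int)
    for i, pk in enumerate(peak_idx):
        lo = peak_idx[i - 1] + 1 if i > 0 else 0
        in_range = cand[(cand >= lo) & (cand < pk)]
        if in_range.size:
            idx = int(in_range[-1])  # latest onset candidate before the peak
        elif pk > lo:
            idx = lo + int(np.argmin(x[lo:pk]))  # fallback: inter-beat minimum
        else:
            logger.info("systolic peak at index %d has no room for an onset; dropped", pk)
            continue
        onsets.append(FiducialPoint(index=idx, time=t0 + idx / fs, amplitude=float(x[idx])))
    return onsets


def detect_systolic_peaks_on(
    x: np.ndarray, fs: float, t0: float, config: DetectorConfig
) -> list[FiducialPoint]:
    """Block detection on a bare array (used for the negated-signal pass)."""
    points = []
    for lo, hi in _detect_blocks(x, fs, config):
        idx = lo + int(np.argmax(x[lo:hi]))
        points.append(FiducialPoint(index=idx, time=t0 + idx / fs, amplitude=float(x[idx])))
    return points


def detect_diastolic_peaks(
    segment,
    systolic_peaks: list[FiducialPoint],
    config: DetectorConfig | None = None,
) -> list[FiducialPoint | None]:
    """Diastolic peak (or None) per beat, via the inverted smoothed second
    derivative.

    The diastolic bump is a region of negative curvature after the systolic
    peak, i.e. a local maximum of the inverted second derivative. The
    search runs from just after the systolic peak to the beat's trough
    (inter-beat minimum — a stand-in for the next onset); candidates must
    clear a prominence floor so second-derivative ripple on bump-free beats
    is not mistaken for a diastolic peak.
    """
    config = config or DetectorConfig()
    x, fs, t0 = _as_array(segment)
    if not systolic_peaks:
        return []
    d2 = np.zeros_like(x)
    d2[1:-1] = np.diff(x, 2)
    w = _window_samples(config.second_derivative_smoothing_window, fs)
    inv_d2 = -uniform_filter1d(d2, w, mode="nearest")
    floor = config.diastolic_prominence_fraction * float(np.ptp(inv_d2))

    peak_idx = [p.index for p in systolic_peaks]
    results: list[FiducialPoint | None] = []
    for i, pk in enumerate(peak_idx):
        end = peak_idx[i + 1] if i + 1 < len(peak_idx) else x.size
        # stop at the beat trough: the diastolic peak precedes the next onset
        if end - pk > 2:
            trough = pk + int(np.argmin(x[pk:end]))
        else:
            trough = end
        lo, hi = pk + 1, max(pk + 2, trough)
        if hi - lo < 3:
            results.append(None)
            continue
        local, _ = sps.find_peaks(inv_d2[lo:hi], prominence=max(floor, 1e-12))
        if local.size == 0:
            results.append(None)
            continue
        idx = lo + int(local[0])  # first qualifying bump after the systolic peak
        results.append(FiducialPoint(index=idx, time=t0 + idx / fs, amplitude=float(x[idx])))
    return results


def assemble_beats(
    pwbs: list[FiducialPoint],
    pwsps: list[FiducialPoint],
    pwdps: list[FiducialPoint | None] | None = None,
) -> list[BeatFiducials]:
    """Pair ordered PWB/PWSP/PWDP lists into complete beats.

    PWE of beat *i* is PWB of beat *i+1*; the final beat, lacking a
    successor, is dropped. Beats violating the time ordering
    pwb < pwsp (< pwdp) < pwe are discarded with a log notice.
    """
    if pwdps is None:
        pwdps = [None] * len(pwsps)
    n = min(len(pwbs), len(pwsps), len(pwdps))
    beats: list[BeatFiducials] = []
    for i in range(n - 1):
        pwb, pwsp, pwdp = pwbs[i], pwsps[i], pwdps[i]
        pwe = pwbs[i + 1]
        if not (pwb.time < pwsp.time < pwe.time):
            logger.info("beat %d dropped: fiducial ordering violated", i)
            continue
        if pwdp is not None and not (pwsp.time < pwdp.time < pwe.time):
            logger.info("beat %d: diastolic point outside beat; recorded absent", i)
            pwdp = None
        beats.append(
            BeatFiducials(
                pwb=pwb,
                pwsp=pwsp,
                pwe=pwe,
                pwdp=pwdp,
                next_pwsp_time=pwsps[i + 1].time if i + 1 < len(pwsps) else None,
            )
        )
    return beats


def delineate(segment, config: DetectorConfig | None = None) -> list[BeatFiducials]:
    """Full delineation of a segment: PWSP, PWB, PWDP detection and beat
    assembly."""
    config = config or DetectorConfig()
    pwsps = detect_systolic_peaks(segment, config)
    if not pwsps:
        return []
    pwbs = detect_pulse_begin(segment, pwsps, config)
    if len(pwbs) != len(pwsps):
        # onsets and peaks must stay paired; re-pair by dropping orphan peaks
        pwsps = [p for p in pwsps if any(b.index < p.index for b in pwbs)]
        pwsps = pwsps[: len(pwbs)]
    pwdps = detect_diastolic_peaks(segment, pwsps, config)
    return assemble_beats(pwbs, pwsps, pwdps)
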