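"""24-acupoint GSR (skin resistance) feature panel.

Raw GSR traces (nominally 5 s at 200 Hz per acupoint) are reduced to a
single median resistance per channel. Twelve bilateral acupoints — the
classical Ryodoraku measurement points — are measured on both sides of the
body, giving 24 channels. The canonical channel order is fixed (acupoint
code order below, left before right) so feature-vector positions are
stable across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "ACUPOINT_CODES",
    "SIDES",
    "CHANNELS",
    "GSRSample",
    "GSRPanel",
    "gsr_median",
    "assemble_panel",
    "bilateral_correlation",
]

#: The 12 bilateral acupoint codes, in canonical order.
ACUPOINT_CODES = (
    "LU9",  # Taiyuan
    "PC7",  # Daling
    "HT7",  # Shenmen
    "SI5",  # Yanggu
    "TE4",  # Yangchi
    "LI5",  # Yangxi
    "BL65",  # Shugu
    "LV3",  # Taichong
    "ST42",  # Chongyang
    "SP3",  # Taibai
    "GB40",  # Qiuxu
    "KD4",  # Dazhong
)

SIDES = ("left", "right")

#: Canonical 24-channel order: each acupoint's left channel, then right.
CHANNELS = tuple(f"{code}_{side}" for code in ACUPOINT_CODES for side in SIDES)


@dataclass(frozen=True)
class GSRSample:
    """Raw resistance trace for one acupoint on one side."""

    acupoint_code: str
    side: str
    samples: np.ndarray  # ohms
    sampling_rate: float = 200.0

    def __post_init__(self) -> None:
        if self.acupoint_code not in ACUPOINT_CODES:
            raise ConfigurationError(f"unknown acupoint code {self.acupoint_code!r}")
        if self.side not in SIDES:
            raise ConfigurationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def channel(self) -> str:
        return f"{self.acupoint_code}_{self.side}"


@dataclass(frozen=True)
class GSRPanel:
    """24 median resistances (ohms) in canonical channel order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (24,):
            raise ConfigurationError("a GSR panel has exactly 24 channels")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ConfigurationError("panel resistances must be positive and finite")

    def __getitem__(self, channel: str) -> float:
        return float(self.values[CHANNELS.index(channel)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CHANNELS, self.values.tolist()))


def gsr_median(sample: GSRSample) -> float:
    """Median resistance of one trace (ohms).

    Even-length inputs use the mean of the two central order statistics.
    Non-positive readings (open contact, ADC glitches) are excluded with a
    warning before taking the median.
    """
    x = sample.samples
    if x.size == 0:
        raise DataFormatError(f"empty GSR trace for {sample.channel}")
    bad = ~np.isfinite(x) | (x <= 0)
    if bad.any():
        logger.warning("%s: excluding %d non-positive/non-finite readings", sample.channel, bad.sum())
        x = x[~bad]
        if x.size == 0:
            raise DataFormatError(f"no valid readings in GSR trace for {sample.channel}")
    return float(np.median(x))


def assemble_panel(samples: list[GSRSample]) -> GSRPanel:
    """Reduce 24 raw traces (one per canonical channel) to a panel."""
    seen: dict[str, float] = {}
    for sample in samples:
        if sample.channel in seen:
            raise DataFormatError(f"duplicate GSR channel {sample.channel}")
        seen[sample.channel] = gsr_median(sample)
    missing = [c for c in CHANNELS if c not in seen]
    if missing:
        raise DataFormatError(f"missing GSR channels: {', '.join(missing)}")
    extra = set(seen) - set(CHANNELS)
    if extra:  # unreachable given GSRSample validation, kept for safety
        raise DataFormatError(f"unknown GSR channels: {sorted(extra)}")
    return GSRPanel(values=np.array([seen[c] for c in CHANNELS]))


def bilateral_correlation(panels: list[GSRPanel]) -> dict[str, float | None]:
    """Pearson correlation between left and right channels per acupoint,
    computed across subjects. Diagnostic for the bilateral-symmetry of
    acupoint resistance; requires at least 3 panels. Zero-variance channels
    yield ``None``.
    """
    if len(panels) < 3:
        raise ConfigurationError("bilateral_correlation needs at least 3 panels")
    values = np.array([p.values for p in panels])  # (n_subjects, 24)
    out: dict[str, float | None] = {}
    for j, code in enumerate(ACUPOINT_CODES):
        left, right = values[:, 2 * j], values[:, 2 * j + 1]
        if np.std(left) == 0 or np.std(right) == 0:
            out[code] = None
        else:
            out[code] = float(np.corrcoef(left, right)[0, 1])
    return out
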