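"""Synthetic PPG recordings, acupoint GSR panels and labeled cohorts.

No public recordings exist for this task, so every downstream stage is
exercised on simulated data. The beat model is a sum of two Gaussian bumps
per cardiac cycle — a systolic component and a delayed, smaller diastolic
component — plus white noise and slow sinusoidal baseline wander. Gaussians
were chosen because the per-beat template has closed-form extrema, which
makes brute-force oracles for the fiducial detector trivial to write.

Cohorts consist of a "wiry pulse" group and a control group. The default
group parameterizations encode the effect directions reported for real
wiry-pulse subjects: a narrower (sharper) systolic peak, a diastolic peak
closer in time to the systolic peak, a weaker second-harmonic content of
the beat shape (driven by the shorter systolic-diastolic delay and smaller
diastolic component), and lower skin resistance at a subset of acupoints
(pericardium, heart and liver channels). The magnitudes are tuning
constants of the generator, not claims about physiology: they are set so
that each modality alone is informative but imperfect, leaving headroom
for fusion to help.

Seeding: one master seed per cohort; subject ``i`` uses
``numpy.random.SeedSequence([master_seed, i])`` so cohorts are reproducible
and subjects are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .errors import ConfigurationError
from .gsrpanel import CHANNELS, GSRPanel
from .preprocess import PPGRecording

__all__ = [
    "PPGSimConfig",
    "GroupParams",
    "CohortConfig",
    "SubjectRecord",
    "beat_template",
    "simulate_ppg",
    "simulate_gsr_panel",
    "simulate_cohort",
    "DEFAULT_WIRY",
    "DEFAULT_CONTROL",
]


@dataclass(frozen=True)
class PPGSimConfig:
    """Parameters of one simulated PPG recording.

    Attributes
    ----------
    duration : float
        Recording length, seconds.
    sampling_rate : float
        Hz (default 25, the pulse-sensor rate emulated here).
    heart_rate : float
        Mean heart rate, beats per minute.
    systolic_amplitude : float
        Height of the systolic bump, arbitrary units.
    diastolic_ratio : float
        Diastolic bump height as a fraction of the systolic amplitude, in
        [0, 1).
    systolic_diastolic_delay : float
        Time from systolic to diastolic bump centre, seconds; must be less
        than the beat period.
    systolic_width, diastolic_width : float
        Gaussian standard deviations of the two bumps, seconds.
    noise_sd : float
        White-noise standard deviation, arbitrary units.
    baseline_wander_amplitude, baseline_wander_frequency : float
        Slow sinusoidal drift (respiration/motion surrogate).
    hr_jitter_sd : float
        Per-beat heart-rate jitter, bpm; makes the inter-beat interval
        non-degenerate.
    seed : int, optional
        RNG seed for noise, wander phase and jitter.
    """

    duration: float
    sampling_rate: float = 25.0
    heart_rate: float = 72.0
    systolic_amplitude: float = 1.0
    diastolic_ratio: float = 0.4
    systolic_diastolic_delay: float = 0.36
    systolic_width: float = 0.13
    diastolic_width: float = 0.17
    noise_sd: float = 0.0
    baseline_wander_amplitude: float = 0.0
    baseline_wander_frequency: float = 0.25
    hr_jitter_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        checks = [
            (self.duration > 0, "duration must be positive"),
            (self.sampling_rate > 0, "sampling_rate must be positive"),
            (self.heart_rate > 0, "heart_rate must be positive"),
            (self.systolic_amplitude > 0, "systolic_amplitude must be positive"),
            (0 <= self.diastolic_ratio < 1, "diastolic_ratio must be in [0, 1)"),
            (self.systolic_width > 0, "systolic_width must be positive"),
            (self.diastolic_width > 0, "diastolic_width must be positive"),
            (self.noise_sd >= 0, "noise_sd must be non-negative"),
            (self.hr_jitter_sd >= 0, "hr_jitter_sd must be non-negative"),
            (
                self.baseline_wander_amplitude >= 0,
                "baseline_wander_amplitude must be non-negative",
            ),
            (
                0 < self.systolic_diastolic_delay < 60.0 / self.heart_rate,
                "systolic_diastolic_delay must be positive and less than the beat period",
            ),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)

    @property
    def beat_period(self) -> float:
        return 60.0 / self.heart_rate


def beat_template(config: PPGSimConfig) -> Callable[[np.ndarray], np.ndarray]:
    """Noise-free single-beat waveform centred on the systolic peak at t=0.

    Returned as a callable so tests can evaluate it on arbitrarily dense
    grids to locate extrema by brute force.
    """
    a = config.systolic_amplitude
    r = config.diastolic_ratio
    d = config.systolic_diastolic_delay
    ws, wd = config.systolic_width, config.diastolic_width

    def template(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return a * np.exp(-0.5 * (t / ws) ** 2) + a * r * np.exp(-0.5 * ((t - d) / wd) ** 2)

    return template


def simulate_ppg(config: PPGSimConfig, rng: np.random.Generator | None = None) -> PPGRecording:
    """Simulate one PPG recording.

    With ``noise_sd = 0``, ``hr_jitter_sd = 0`` and no baseline wander the
    output is exactly periodic with period 60/heart_rate s; each period
    contains one global maximum (the systolic peak) and, when the diastolic
    component is present and separated, one secondary local maximum.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t_end = n / fs
    template = beat_template(config)
    period = config.beat_period

    # Beat peak times: first systolic peak at half a period, subsequent
    # peaks spaced by jittered periods. One extra beat on each side keeps
    # the window edges free of truncation artifacts.
    tail = config.systolic_diastolic_delay + 6 * max(
        config.systolic_width, config.diastolic_width
    )
    peak_times = [period / 2 - period]  # one pre-beat
    while peak_times[-1] < t_end + tail:
        hr = config.heart_rate
        if config.hr_jitter_sd > 0:
            hr = max(20.0, hr + config.hr_jitter_sd * rng.standard_normal())
        peak_times.append(peak_times[-1] + 60.0 / hr)

    t = np.arange(n) / fs
    x = np.zeros(n)
    half_span = tail + 6 * config.systolic_width
    for pk in peak_times:
        lo = max(0, int(np.ceil((pk - half_span) * fs)))
        hi = min(n, int(np.floor((pk + half_span) * fs)) + 1)
        if hi > lo:
            x[lo:hi] += template(t[lo:hi] - pk)

    phase = rng.uniform(0, 2 * np.pi)
    if config.baseline_wander_amplitude > 0:
        x += config.baseline_wander_amplitude * np.sin(
            2 * np.pi * config.baseline_wander_frequency * t + phase
        )
    if config.noise_sd > 0:
        x += config.noise_sd * rng.standard_normal(n)
    return PPGRecording(samples=x, sampling_rate=fs)


def simulate_gsr_panel(
    group_params: Mapping[str, tuple[float, float]] | np.ndarray,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    bilateral_correlation: float = 0.9,
) -> GSRPanel:
    """Draw one subject's 24-channel acupoint resistance panel.

    ``group_params`` gives a (location, scale) pair per canonical channel —
    either a mapping keyed by channel name or an array of shape (24, 2).
    Left/right channels of the same acupoint share a latent factor so their
    across-subject correlation equals ``bilateral_correlation`` (real
    bilateral acupoint resistances are strongly correlated).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(group_params, Mapping):
        missing = [c for c in CHANNELS if c not in group_params]
        if missing:
            raise ConfigurationError(f"missing GSR channel parameters: {missing}")
        params = np.array([group_params[c] for c in CHANNELS], dtype=float)
    else:
        params = np.asarray(group_params, dtype=float)
    if params.shape != (24, 2):
        raise ConfigurationError("group_params must provide 24 (location, scale) pairs")
    loc, scale = params[:, 0], params[:, 1]
    if np.any(scale < 0):
        raise ConfigurationError("GSR scale parameters must be non-negative")
    if not 0 <= bilateral_correlation <= 1:
        raise ConfigurationError("bilateral_correlation must be in [0, 1]")

    rho = bilateral_correlation
    shared = rng.standard_normal(12)
    indep = rng.standard_normal(24)
    z = np.sqrt(rho) * np.repeat(shared, 2) + np.sqrt(1 - rho) * indep
    values = loc + scale * z
    # Resistances are physically positive; with realistic locations/scales
    # this floor is never hit.
    values = np.maximum(values, 1.0)
    return GSRPanel(values=values)


@dataclass(frozen=True)
class GroupParams:
    """Per-group distributions of the subject-level simulation parameters.

    PPG morphology parameters are drawn per subject from independent
    normals (mean, sd), truncated to the valid range; GSR panels are drawn
    per subject from per-channel (location, scale) normals with a shared
    bilateral factor.
    """

    heart_rate: tuple[float, float] = (70.0, 7.0)
    systolic_width: tuple[float, float] = (0.140, 0.010)
    diastolic_width: tuple[float, float] = (0.100, 0.010)
    diastolic_ratio: tuple[float, float] = (0.45, 0.06)
    systolic_diastolic_delay: tuple[float, float] = (0.40, 0.040)
    gsr_location: np.ndarray = field(default=None)  # ohms, shape (24,)
    gsr_scale: np.ndarray = field(default=None)  # ohms, shape (24,)
    noise_sd: float = 0.03
    baseline_wander_amplitude: float = 0.10
    baseline_wander_frequency: float = 0.25
    hr_jitter_sd: float = 2.0
    bilateral_correlation: float = 0.9

    def __post_init__(self) -> None:
        if self.gsr_location is None or self.gsr_scale is None:
            raise ConfigurationError("gsr_location and gsr_scale are required (24 values each)")
        object.__setattr__(self, "gsr_location", np.asarray(self.gsr_location, dtype=float))
        object.__setattr__(self, "gsr_scale", np.asarray(self.gsr_scale, dtype=float))
        if self.gsr_location.shape != (24,) or self.gsr_scale.shape != (24,):
            raise ConfigurationError("gsr_location and gsr_scale must have shape (24,)")


# Baseline acupoint resistances (ohms) per canonical channel: plausible
# Ryodoraku-style skin resistances of a few hundred kilo-ohms, varying by
# location; identical for left and right.
_BASE_KOHM = {
    "LU9": 420.0,
    "PC7": 380.0,
    "HT7": 350.0,
    "SI5": 300.0,
    "TE4": 320.0,
    "LI5": 340.0,
    "BL65": 260.0,
    "LV3": 450.0,
    "ST42": 310.0,
    "SP3": 280.0,
    "GB40": 330.0,
    "KD4": 290.0,
}
_GSR_LOCATION = np.array([_BASE_KOHM[c.rsplit("_", 1)[0]] for c in CHANNELS]) * 1e3
_GSR_SCALE = 0.20 * _GSR_LOCATION  # 20% between-subject spread

# Wiry-group resistance shift: lower resistance (higher conductance, a
# stress correlate) at the pericardium, heart and liver channels.
_WIRY_GSR_MULT = np.full(24, 0.88)  # global sympathetic shift
for _i, _c in enumerate(CHANNELS):
    _code = _c.rsplit("_", 1)[0]
    if _code == "LV3":
        _WIRY_GSR_MULT[_i] = 0.78
    elif _code in ("PC7", "HT7"):
        _WIRY_GSR_MULT[_i] = 0.85

DEFAULT_CONTROL = GroupParams(gsr_location=_GSR_LOCATION, gsr_scale=_GSR_SCALE)
DEFAULT_WIRY = GroupParams(
    heart_rate=(74.0, 7.0),
    systolic_width=(0.120, 0.010),
    diastolic_ratio=(0.25, 0.06),
    systolic_diastolic_delay=(0.32, 0.040),
    gsr_location=_GSR_LOCATION * _WIRY_GSR_MULT,
    gsr_scale=_GSR_SCALE,
)


@dataclass(frozen=True)
class CohortConfig:
    """A labeled two-group cohort: ``n_wiry`` positive and ``n_control``
    negative subjects, each with one PPG recording and one GSR panel."""

    n_wiry: int = 40
    n_control: int = 40
    duration: float = 300.0
    sampling_rate: float = 25.0
    wiry: GroupParams = field(default_factory=lambda: DEFAULT_WIRY)
    control: GroupParams = field(default_factory=lambda: DEFAULT_CONTROL)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wiry < 0 or self.n_control < 0:
            raise ConfigurationError("group sizes must be non-negative")
        if self.n_wiry + self.n_control < 2:
            raise ConfigurationError("a cohort needs at least 2 subjects")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: PPG recording, GSR panel, binary label (1 = wiry)."""

    subject_id: str
    label: int
    recording: PPGRecording
    gsr_panel: GSRPanel
    sim_params: PPGSimConfig | None = None  # ground truth, for diagnostics


def _draw_subject_config(
    group: GroupParams, cohort: CohortConfig, rng: np.random.Generator
) -> PPGSimConfig:
    def normal(mean_sd: tuple[float, float], lo: float, hi: float) -> float:
        mean, sd = mean_sd
        return float(np.clip(mean + sd * rng.standard_normal(), lo, hi))

    hr = normal(group.heart_rate, 40.0, 160.0)
    period = 60.0 / hr
    return PPGSimConfig(
        duration=cohort.duration,
        sampling_rate=cohort.sampling_rate,
        heart_rate=hr,
        diastolic_ratio=normal(group.diastolic_ratio, 0.05, 0.9),
        diastolic_width=normal(group.diastolic_width, 0.05, 0.25),
        # cap the delay so the diastolic bump stays clear of the next onset
        systolic_diastolic_delay=normal(
            group.systolic_diastolic_delay, 0.12, 0.55 * period
        ),
        systolic_width=normal(group.systolic_width, 0.06, 0.30),
        noise_sd=group.noise_sd,
        baseline_wander_amplitude=group.baseline_wander_amplitude,
        baseline_wander_frequency=group.baseline_wander_frequency,
        hr_jitter_sd=group.hr_jitter_sd,
    )


def simulate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate a labeled cohort, wiry subjects first.

    Fully reproducible: subject ``i`` uses
    ``SeedSequence([config.seed, i])``, so the same config and seed give
    byte-identical recordings and panels.
    """
    records: list[SubjectRecord] = []
    n_total = config.n_wiry + config.n_control
    for i in range(n_total):
        wiry = i < config.n_wiry
        group = config.wiry if wiry else config.control
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        sim = _draw_subject_config(group, config, rng)
        recording = simulate_ppg(sim, rng=rng)
        panel = simulate_gsr_panel(
            np.column_stack([group.gsr_location, group.gsr_scale]),
            rng=rng,
            bilateral_correlation=group.bilateral_correlation,
        )
        subject_id = f"S{i:03d}"
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                label=int(wiry),
                recording=replace(recording, subject_id=subject_id),
                gsr_panel=panel,
                sim_params=sim,
            )
        )
    return records
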