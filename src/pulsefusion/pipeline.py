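"""End-to-end pipeline: simulate (or ingest) -> preprocess -> features ->
classify, with a validated configuration document and an atomically written
run manifest.

All randomness flows from ``PipelineConfig.seed``; re-running the same
config reproduces every numeric output.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
import time
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .errors import ConfigurationError
from .fiducials import DetectorConfig
from .io import read_cohort_manifest, write_cohort
from .model import (
    FEATURE_SUBSETS,
    ModelConfig,
    ablation_table,
    extract_cohort_features,
    feature_importance,
)
from .synth import CohortConfig, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


class FCNSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hidden_layers: tuple[int, ...] = (30, 30, 30)
    activation: str = "relu"
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "pulsefusion_run"
    cohort_manifest: str | None = None  # ingest instead of simulating
    n_wiry: int = 8
    n_control: int = 8
    duration: float = 300.0  # seconds of PPG per subject
    sampling_rate: float = 25.0
    window: float = 10.0  # sliding-window length, s
    hop: float = 1.0  # sliding-window hop, s
    band_low: float = 0.5  # bandpass corners, Hz
    band_high: float = 8.0
    use_pmaf: bool = True
    pmaf_k: int = 3
    ma_peak_window: float = 0.111  # detector constants, s
    ma_beat_window: float = 0.667
    k_folds: int = 5
    subsets: tuple[str, ...] = ("gsr24", "ppg18", "all42")
    importance: bool = True
    write_recordings: bool = False
    fcn: FCNSettings = Field(default_factory=FCNSettings)
    seed: int = 0

    @field_validator("subsets")
    @classmethod
    def _known_subsets(cls, value):
        unknown = [s for s in value if s not in FEATURE_SUBSETS]
        if unknown:
            raise ValueError(f"unknown feature subsets: {unknown}")
        return value


class RunManifest(BaseModel):
    """What a run did: config snapshot, versions, per-stage counts and
    timings, warnings. Written atomically at the end of the run."""

    config: PipelineConfig
    version: str
    stage_counts: dict[str, int]
    timings_s: dict[str, float]
    warnings: list[str]


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as handle:
        handle.write(text)
    os.replace(tmp, path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages and write all artifacts to
    ``config.out_dir`` (metrics JSON, ablation CSV, importance CSV, fold
    CSV, manifest JSON)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    notices: list[str] = []

    tic = time.perf_counter()
    if config.cohort_manifest:
        records = read_cohort_manifest(config.cohort_manifest)
    else:
        records = simulate_cohort(
            CohortConfig(
                n_wiry=config.n_wiry,
                n_control=config.n_control,
                duration=config.duration,
                sampling_rate=config.sampling_rate,
                seed=config.seed,
            )
        )
        if config.write_recordings:
            write_cohort(records, out_dir / "cohort")
    counts["subjects"] = len(records)
    timings["cohort"] = time.perf_counter() - tic
    logger.info("cohort ready: %d subjects", len(records))

    tic = time.perf_counter()
    detector = DetectorConfig(
        ma_peak_window=config.ma_peak_window, ma_beat_window=config.ma_beat_window
    )
    subjects = extract_cohort_features(
        records,
        window=config.window,
        hop=config.hop,
        detector_config=detector,
        band=(config.band_low, config.band_high),
        use_pmaf=config.use_pmaf,
        pmaf_k=config.pmaf_k,
    )
    n_segments = sum(len(s.ppg) for s in subjects)
    expected = len(records) * int((config.duration - config.window) // config.hop)
    counts["segments_valid"] = n_segments
    counts["segments_invalid"] = expected - n_segments
    counts["segments_per_subject"] = int((config.duration - config.window) // config.hop)
    if expected != n_segments:
        notices.append(f"{expected - n_segments} segments flagged invalid and excluded")
    timings["features"] = time.perf_counter() - tic
    logger.info("features extracted: %d valid segments", n_segments)

    tic = time.perf_counter()
    model_config = ModelConfig(
        hidden_layers=config.fcn.hidden_layers,
        activation=config.fcn.activation,
        epochs=config.fcn.epochs,
        learning_rate=config.fcn.learning_rate,
        batch_size=config.fcn.batch_size,
        seed=config.seed,
    )
    table = ablation_table(
        subjects, model_config, k=config.k_folds, seed=config.seed, subsets=config.subsets
    )
    table.to_csv(out_dir / "ablation.csv", index=False)
    splitter = StratifiedKFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
    ids = [s.subject_id for s in subjects]
    labels = [s.label for s in subjects]
    folds = [
        {"subject_id": ids[i], "fold": fold}
        for fold, (_, test_ix) in enumerate(splitter.split(ids, labels))
        for i in test_ix
    ]
    _atomic_write(out_dir / "folds.json", json.dumps(folds, indent=2))
    metrics = {
        row["feature_subset"]: {
            "segment_accuracy": row["segment_accuracy"],
            "subject_accuracy": row["subject_accuracy"],
        }
        for _, row in table.iterrows()
    }
    timings["model"] = time.perf_counter() - tic

    if config.importance:
        tic = time.perf_counter()
        report = feature_importance(subjects, "all42", seed=config.seed)
        report.table.to_csv(out_dir / "importance.csv", index=False)
        metrics["top_features"] = report.ranking[:3]
        timings["importance"] = time.perf_counter() - tic

    _atomic_write(out_dir / "metrics.json", json.dumps(metrics, indent=2))
    manifest = RunManifest(
        config=config,
        version=__version__,
        stage_counts=counts,
        timings_s={k: round(v, 3) for k, v in timings.items()},
        warnings=notices,
    )
    _atomic_write(out_dir / "manifest.json", manifest.model_dump_json(indent=2))
    return manifest


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a JSON config file, applying keyword overrides."""
    raw = json.loads(Path(path).read_text()) if path else {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**raw)
    except Exception as exc:  # pydantic ValidationError -> user error
        raise ConfigurationError(str(exc)) from exc
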