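"""Sensor-fusion classifier: 42-feature rows, subject-level cross-validation,
modality ablations, and random-forest feature importance.

Each subject contributes one row per valid 10-s PPG segment (nominally 290
rows from a 5-min recording). A row fuses the 18 PPG features of that
segment with the subject's 24 GSR medians, which are constant across all
of a subject's rows. The classifier is a fully connected network with
three 30-neuron hidden layers and a single logistic output; inputs are
z-scored with parameters fitted on training subjects only.

Cross-validation always splits by *subject* (stratified by label), never by
segment: segments of one subject are strongly dependent, and the constant
GSR block would otherwise leak labels into the test folds. Subject-level
predictions average the subject's segment probabilities and threshold at
0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError
from .features import HARMONIC_FEATURE_NAMES, PPG_FEATURE_NAMES, TIME_FEATURE_NAMES
from .gsrpanel import CHANNELS

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_SUBSETS",
    "SubjectFeatures",
    "ModelConfig",
    "CVResult",
    "ImportanceReport",
    "TrainedModel",
    "extract_cohort_features",
    "build_feature_matrix",
    "train_fcn",
    "cross_validate",
    "ablation_table",
    "feature_importance",
    "evaluate_holdout",
]

GSR_FEATURE_NAMES = CHANNELS

#: The seven feature subsets compared in the modality ablation.
FEATURE_SUBSETS: dict[str, tuple[str, ...]] = {
    "gsr24": GSR_FEATURE_NAMES,
    "ppg18": PPG_FEATURE_NAMES,
    "time8": TIME_FEATURE_NAMES,
    "freq10": HARMONIC_FEATURE_NAMES,
    "time8+gsr": TIME_FEATURE_NAMES + GSR_FEATURE_NAMES,
    "freq10+gsr": HARMONIC_FEATURE_NAMES + GSR_FEATURE_NAMES,
    "all42": PPG_FEATURE_NAMES + GSR_FEATURE_NAMES,
}


@dataclass(frozen=True)
class SubjectFeatures:
    """One subject's extracted features: a per-segment PPG feature table
    (columns f1..f8, c1..c10) and the 24-value GSR panel."""

    subject_id: str
    label: int
    ppg: pd.DataFrame
    gsr: np.ndarray  # shape (24,), ohms

    def __post_init__(self) -> None:
        object.__setattr__(self, "gsr", np.asarray(self.gsr, dtype=float))
        if self.gsr.shape != (24,):
            raise ConfigurationError("gsr must have 24 values")


@dataclass(frozen=True)
class ModelConfig:
    """FCN hyperparameters. The architecture (42 -> 30 -> 30 -> 30 -> 1
    with a logistic output) is fixed by design; optimizer settings are
    free choices."""

    hidden_layers: tuple[int, ...] = (30, 30, 30)
    activation: str = "relu"
    epochs: int = 120
    learning_rate: float = 1e-3
    batch_size: int = 128
    alpha: float = 5.0
    seed: int = 0


@dataclass(frozen=True)
class CVResult:
    """Per-fold and aggregate accuracies of one cross-validation run."""

    fold_segment_accuracy: list[float]
    fold_subject_accuracy: list[float]
    fold_assignments: dict[str, int]
    seed: int

    @property
    def mean_segment_accuracy(self) -> float:
        return float(np.mean(self.fold_segment_accuracy))

    @property
    def mean_subject_accuracy(self) -> float:
        return float(np.mean(self.fold_subject_accuracy))


@dataclass(frozen=True)
class TrainedModel:
    """A fitted scaler+FCN pipeline bound to its feature columns."""

    pipeline: Pipeline
    columns: tuple[str, ...]
    subset: str

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in rows.columns]
        if missing:
            raise ConfigurationError(f"feature columns missing from input: {missing}")
        return self.pipeline.predict_proba(rows.loc[:, list(self.columns)].to_numpy())[:, 1]


@dataclass(frozen=True)
class ImportanceReport:
    """Random-forest impurity importances with per-group statistics.

    ``table`` has one row per feature, sorted by weight: columns are
    feature, weight, wiry_mean, wiry_std, control_mean, control_std,
    p_value (Welch two-sample t-test on per-subject means; NaN when a
    feature is constant).
    """

    table: pd.DataFrame
    seed: int

    @property
    def ranking(self) -> list[str]:
        return self.table["feature"].tolist()


def build_feature_matrix(
    subjects: list[SubjectFeatures],
    feature_subset: str = "all42",
) -> pd.DataFrame:
    """One row per valid segment: meta columns (subject_id, segment_index,
    label) followed by the subset's feature columns, with the subject's GSR
    block replicated across all their rows."""
    if feature_subset not in FEATURE_SUBSETS:
        raise ConfigurationError(
            f"unknown feature subset {feature_subset!r}; choose from {sorted(FEATURE_SUBSETS)}"
        )
    columns = FEATURE_SUBSETS[feature_subset]
    frames = []
    for subject in subjects:
        if subject.ppg.empty:
            logger.warning("subject %s has no valid segments; excluded", subject.subject_id)
            continue
        block = subject.ppg.copy()
        block["subject_id"] = subject.subject_id
        block["label"] = subject.label
        for name, value in zip(GSR_FEATURE_NAMES, subject.gsr):
            block[name] = value
        frames.append(block)
    if not frames:
        raise ConfigurationError("no subjects with valid segments")
    matrix = pd.concat(frames, ignore_index=True)
    meta = ["subject_id", "segment_index", "label"]
    return matrix.loc[:, meta + list(columns)]


def _make_pipeline(config: ModelConfig, n_features: int) -> Pipeline:
    mlp = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_layers),
        activation=config.activation,
        solver="adam",
        learning_rate_init=config.learning_rate,
        batch_size=config.batch_size,
        max_iter=config.epochs,
        alpha=config.alpha,
        random_state=config.seed,
    )
    return Pipeline([("scale", StandardScaler()), ("fcn", mlp)])


def train_fcn(rows: pd.DataFrame, config: ModelConfig | None = None,
              feature_subset: str = "all42") -> TrainedModel:
    """Fit the scaler + fully connected network on feature rows.

    Deterministic given ``config.seed``. Raises if only one class is
    present.
    """
    config = config or ModelConfig()
    columns = FEATURE_SUBSETS[feature_subset]
    y = rows["label"].to_numpy()
    if np.unique(y).size < 2:
        raise ConfigurationError("training rows must contain both classes")
    X = rows.loc[:, list(columns)].to_numpy()
    pipeline = _make_pipeline(config, X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipeline.fit(X, y)
    return TrainedModel(pipeline=pipeline, columns=columns, subset=feature_subset)


def _subject_table(subjects: list[SubjectFeatures]) -> tuple[np.ndarray, np.ndarray]:
    ids = np.array([s.subject_id for s in subjects])
    labels = np.array([s.label for s in subjects])
    return ids, labels


def _subject_accuracy(rows: pd.DataFrame, probs: np.ndarray) -> float:
    frame = rows.loc[:, ["subject_id", "label"]].copy()
    frame["prob"] = probs
    per_subject = frame.groupby("subject_id", sort=False).agg(
        prob=("prob", "mean"), label=("label", "first")
    )
    predictions = (per_subject["prob"] >= 0.5).astype(int)
    return float((predictions == per_subject["label"]).mean())


def cross_validate(
    subjects: list[SubjectFeatures],
    feature_subset: str = "all42",
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation split by subject.

    With 80 balanced subjects and k=5 each test fold holds 16 subjects, 8
    per class, and each model trains on all segments of the other 64.
    """
    config = config or ModelConfig()
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if len(subjects) < k:
        raise ConfigurationError(f"{len(subjects)} subjects cannot form {k} folds")
    matrix = build_feature_matrix(subjects, feature_subset)
    ids, labels = _subject_table(subjects)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    seg_acc, subj_acc = [], []
    assignments: dict[str, int] = {}
    for fold, (train_ix, test_ix) in enumerate(splitter.split(ids, labels)):
        train_ids, test_ids = set(ids[train_ix]), set(ids[test_ix])
        for sid in test_ids:
            assignments[sid] = fold
        train_rows = matrix[matrix["subject_id"].isin(train_ids)]
        test_rows = matrix[matrix["subject_id"].isin(test_ids)]
        model = train_fcn(train_rows, config, feature_subset)
        probs = model.predict_proba(test_rows)
        seg_acc.append(float(((probs >= 0.5).astype(int) == test_rows["label"]).mean()))
        subj_acc.append(_subject_accuracy(test_rows, probs))
    return CVResult(
        fold_segment_accuracy=seg_acc,
        fold_subject_accuracy=subj_acc,
        fold_assignments=assignments,
        seed=seed,
    )


def ablation_table(
    subjects: list[SubjectFeatures],
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
    subsets: tuple[str, ...] = tuple(FEATURE_SUBSETS),
) -> pd.DataFrame:
    """Cross-validate every feature subset with shared folds (same seed, so
    identical subject splits) and tabulate segment- and subject-level
    accuracies."""
    rows = []
    for subset in subsets:
        result = cross_validate(subjects, subset, config, k=k, seed=seed)
        rows.append(
            {
                "feature_subset": subset,
                "n_features": len(FEATURE_SUBSETS[subset]),
                "segment_accuracy": result.mean_segment_accuracy,
                "subject_accuracy": result.mean_subject_accuracy,
            }
        )
    return pd.DataFrame(rows)


def feature_importance(
    subjects: list[SubjectFeatures],
    feature_subset: str = "all42",
    n_estimators: int = 500,
    seed: int = 0,
) -> ImportanceReport:
    """Impurity-based importance from a random forest, with group means and
    Welch t-test p-values.

    The forest and the statistics operate on per-subject feature averages
    (one row per subject) so that the 290-fold replication of segments does
    not overstate the evidence.
    """
    matrix = build_feature_matrix(subjects, feature_subset)
    columns = list(FEATURE_SUBSETS[feature_subset])
    per_subject = matrix.groupby("subject_id", sort=False).agg(
        {**{c: "mean" for c in columns}, "label": "first"}
    )
    y = per_subject["label"].to_numpy()
    if np.unique(y).size < 2:
        raise ConfigurationError("both classes are required for feature importance")
    X = per_subject.loc[:, columns].to_numpy()
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(X, y)
    weights = forest.feature_importances_

    wiry, control = X[y == 1], X[y == 0]
    records = []
    for j, name in enumerate(columns):
        if np.ptp(X[:, j]) == 0:
            p_value = float("nan")
        else:
            p_value = float(stats.ttest_ind(wiry[:, j], control[:, j], equal_var=False).pvalue)
        records.append(
            {
                "feature": name,
                "weight": float(weights[j]),
                "wiry_mean": float(wiry[:, j].mean()),
                "wiry_std": float(wiry[:, j].std(ddof=1)),
                "control_mean": float(control[:, j].mean()),
                "control_std": float(control[:, j].std(ddof=1)),
                "p_value": p_value,
            }
        )
    table = pd.DataFrame(records).sort_values("weight", ascending=False, ignore_index=True)
    return ImportanceReport(table=table, seed=seed)


def extract_cohort_features(records, **extract_kwargs) -> list[SubjectFeatures]:
    """Run PPG feature extraction for every subject record (any object with
    ``subject_id``, ``label``, ``recording`` and ``gsr_panel``) and bundle
    the results with the GSR panels."""
    from .features import extract_recording_features

    out = []
    for record in records:
        ppg = extract_recording_features(record.recording, **extract_kwargs)
        out.append(
            SubjectFeatures(
                subject_id=record.subject_id,
                label=record.label,
                ppg=ppg.drop(columns=["subject_id"]),
                gsr=record.gsr_panel.values,
            )
        )
    return out


def evaluate_holdout(model: TrainedModel, subjects: list[SubjectFeatures]) -> float:
    """Subject-level accuracy of a frozen model (including its frozen
    standardization) on unseen subjects."""
    if not subjects:
        raise ConfigurationError("holdout set is empty")
    matrix = build_feature_matrix(subjects, model.subset)
    probs = model.predict_proba(matrix)
    return _subject_accuracy(matrix, probs)
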