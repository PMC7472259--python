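import numpy as np
import pandas as pd
import pytest

from pulsefusion.errors import ConfigurationError
from pulsefusion.features import PPG_FEATURE_NAMES
from pulsefusion.model import (
    FEATURE_SUBSETS,
    ModelConfig,
    SubjectFeatures,
    ablation_table,
    build_feature_matrix,
    cross_validate,
    evaluate_holdout,
    feature_importance,
    train_fcn,
)

FAST = ModelConfig(epochs=40, batch_size=32, seed=0)


def make_subjects(
    n_pos: int,
    n_neg: int,
    n_segments: int = 6,
    ppg_shift: float = 0.0,
    gsr_shift: float = 0.0,
    seed: int = 0,
    shifted_feature: str | None = None,
) -> list[SubjectFeatures]:
    """Fabricated cohorts: PPG features are subject-level Gaussians plus
    per-segment noise; GSR panels are constant per subject. Group shifts are
    applied to all PPG features (or one named feature) and all GSR channels."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_pos + n_neg):
        label = int(i < n_pos)
        center = rng.standard_normal(18)
        if label:
            if shifted_feature is not None:
                center[PPG_FEATURE_NAMES.index(shifted_feature)] += ppg_shift
            else:
                center = center + ppg_shift
        ppg = pd.DataFrame(
            center + 0.3 * rng.standard_normal((n_segments, 18)),
            columns=PPG_FEATURE_NAMES,
        )
        ppg.insert(0, "segment_index", np.arange(n_segments))
        gsr = 4e5 + 5e4 * rng.standard_normal(24) + label * gsr_shift
        gsr = np.maximum(gsr, 1.0)
        subjects.append(
            SubjectFeatures(subject_id=f"T{i:03d}", label=label, ppg=ppg, gsr=gsr)
        )
    return subjects


class TestFeatureMatrix:
    def test_fused_width_and_row_count(self):
        subjects = make_subjects(4, 4, n_segments=10)
        matrix = build_feature_matrix(subjects, "all42")
        assert matrix.shape == (80, 3 + 42)

    @pytest.mark.parametrize(
        "subset,width", [("gsr24", 24), ("ppg18", 18), ("time8", 8), ("freq10", 10),
                         ("time8+gsr", 32), ("freq10+gsr", 34)]
    )
    def test_subset_widths(self, subset, width):
        matrix = build_feature_matrix(make_subjects(2, 2), subset)
        assert matrix.shape[1] == 3 + width
        assert len(FEATURE_SUBSETS[subset]) == width

    def test_gsr_block_identical_across_a_subjects_rows(self):
        matrix = build_feature_matrix(make_subjects(2, 2, n_segments=8), "gsr24")
        for _, group in matrix.groupby("subject_id"):
            assert (group.iloc[:, 3:].nunique() == 1).all()

    def test_subject_without_segments_excluded(self):
        subjects = make_subjects(2, 2)
        empty = SubjectFeatures(
            subject_id="EMPTY", label=1,
            ppg=subjects[0].ppg.iloc[:0], gsr=subjects[0].gsr,
        )
        matrix = build_feature_matrix(subjects + [empty], "all42")
        assert "EMPTY" not in set(matrix.subject_id)

    def test_unknown_subset_rejected(self):
        with pytest.raises(ConfigurationError):
            build_feature_matrix(make_subjects(2, 2), "all43")


class TestTrainFCN:
    def test_separable_clouds_reach_high_training_accuracy(self):
        subjects = make_subjects(10, 10, n_segments=20, ppg_shift=3.0, seed=1)
        rows = build_feature_matrix(subjects, "ppg18")
        model = train_fcn(rows, FAST, "ppg18")
        predictions = (model.predict_proba(rows) >= 0.5).astype(int)
        assert (predictions == rows.label).mean() >= 0.99

    def test_deterministic_given_seed(self):
        subjects = make_subjects(5, 5, ppg_shift=1.0, seed=2)
        rows = build_feature_matrix(subjects, "all42")
        a = train_fcn(rows, FAST, "all42")
        b = train_fcn(rows, FAST, "all42")
        np.testing.assert_array_equal(a.predict_proba(rows), b.predict_proba(rows))
        for wa, wb in zip(a.pipeline["fcn"].coefs_, b.pipeline["fcn"].coefs_):
            np.testing.assert_array_equal(wa, wb)

    def test_single_class_rejected(self):
        rows = build_feature_matrix(make_subjects(4, 4), "all42")
        with pytest.raises(ConfigurationError):
            train_fcn(rows[rows.label == 1], FAST, "all42")

    def test_shuffled_labels_give_chance_level_cv(self):
        """Permutation null: with labels randomly reassigned, cross-validated
        accuracy averages to chance (single permutations on 40 subjects keep
        sampling noise, so average over three)."""
        accs = []
        for seed in (3, 13, 23):
            subjects = make_subjects(20, 20, n_segments=6, ppg_shift=2.0, seed=seed)
            rng = np.random.default_rng(seed)
            labels = rng.permutation([s.label for s in subjects])
            shuffled = [
                SubjectFeatures(s.subject_id, int(l), s.ppg, s.gsr)
                for s, l in zip(subjects, labels)
            ]
            result = cross_validate(shuffled, "all42", FAST, k=5, seed=seed)
            accs.append(result.mean_subject_accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_standardization_fitted_on_training_rows_only(self):
        """No leakage: the scaler state must reflect training rows alone,
        even when held-out rows contain wild values."""
        subjects = make_subjects(4, 4)
        matrix = build_feature_matrix(subjects, "all42")
        train_rows = matrix[matrix.subject_id != "T000"]
        model = train_fcn(train_rows, FAST, "all42")
        cols = list(FEATURE_SUBSETS["all42"])
        np.testing.assert_allclose(
            model.pipeline["scale"].mean_, train_rows[cols].mean().to_numpy()
        )


class TestCrossValidation:
    def test_fold_design_80_subjects(self):
        subjects = make_subjects(40, 40, n_segments=3, ppg_shift=1.0, seed=4)
        result = cross_validate(subjects, "ppg18", FAST, k=5, seed=4)
        folds = pd.Series(result.fold_assignments)
        labels = {s.subject_id: s.label for s in subjects}
        assert sorted(folds.index) == sorted(labels)  # partition of subjects
        for fold, members in folds.groupby(folds):
            assert len(members) == 16
            assert sum(labels[sid] for sid in members.index) == 8  # 8 per class

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            cross_validate(make_subjects(2, 2), "all42", FAST, k=5)

    def test_subject_accuracy_invariant_to_segment_order(self):
        subjects = make_subjects(6, 6, ppg_shift=1.5, seed=5)
        shuffled = [
            SubjectFeatures(
                s.subject_id, s.label,
                s.ppg.sample(frac=1.0, random_state=9).reset_index(drop=True), s.gsr,
            )
            for s in subjects
        ]
        a = cross_validate(subjects, "ppg18", FAST, k=3, seed=5)
        b = cross_validate(shuffled, "ppg18", FAST, k=3, seed=5)
        assert a.fold_subject_accuracy == b.fold_subject_accuracy


class TestAblation:
    def test_gsr_only_signal_ranks_gsr_subset_first(self):
        subjects = make_subjects(12, 12, gsr_shift=8e4, seed=6)
        table = ablation_table(subjects, FAST, k=3, seed=6,
                               subsets=("gsr24", "ppg18")).set_index("feature_subset")
        assert (
            table.loc["gsr24", "subject_accuracy"] > table.loc["ppg18", "subject_accuracy"]
        )

    def test_shared_folds_across_subsets(self):
        subjects = make_subjects(6, 6, seed=7)
        a = cross_validate(subjects, "gsr24", FAST, k=3, seed=7)
        b = cross_validate(subjects, "ppg18", FAST, k=3, seed=7)
        assert a.fold_assignments == b.fold_assignments


class TestImportance:
    def test_weights_sum_to_one(self):
        report = feature_importance(make_subjects(10, 10, ppg_shift=1.0, seed=8), seed=8)
        assert report.table.weight.sum() == pytest.approx(1.0, abs=1e-9)
        assert (report.table.weight >= 0).all()

    def test_single_discriminative_feature_ranks_first(self):
        subjects = make_subjects(
            15, 15, n_segments=4, ppg_shift=4.0, shifted_feature="f2", seed=9
        )
        report = feature_importance(subjects, "ppg18", seed=9)
        assert report.ranking[0] == "f2"

    def test_pure_noise_importances_stay_diffuse(self):
        for seed in range(10):
            report = feature_importance(
                make_subjects(40, 40, seed=100 + seed), "all42", n_estimators=200, seed=seed
            )
            assert report.table.weight.max() < 2 / 42 + 0.05

    def test_constant_feature_gets_zero_weight_and_no_pvalue(self):
        subjects = make_subjects(6, 6, seed=10)
        frozen = [
            SubjectFeatures(s.subject_id, s.label, s.ppg.assign(f1=1.0), s.gsr)
            for s in subjects
        ]
        report = feature_importance(frozen, "ppg18", seed=10)
        row = report.table.set_index("feature").loc["f1"]
        assert row.weight == 0.0
        assert np.isnan(row.p_value)


class TestHoldout:
    def test_holdout_from_same_distribution_tracks_cv(self):
        train = make_subjects(12, 12, ppg_shift=2.0, seed=11)
        rows = build_feature_matrix(train, "ppg18")
        model = train_fcn(rows, FAST, "ppg18")
        holdout = make_subjects(6, 6, ppg_shift=2.0, seed=99)
        assert evaluate_holdout(model, holdout) >= 0.8

    def test_training_subject_predicted_consistently(self):
        train = make_subjects(6, 6, ppg_shift=2.0, seed=12)
        rows = build_feature_matrix(train, "ppg18")
        model = train_fcn(rows, FAST, "ppg18")
        single = [train[0]]
        probs = model.predict_proba(build_feature_matrix(single, "ppg18"))
        expected = model.predict_proba(rows[rows.subject_id == train[0].subject_id])
        np.testing.assert_array_equal(probs, expected)

    def test_empty_holdout_rejected(self):
        train = make_subjects(4, 4, seed=13)
        model = train_fcn(build_feature_matrix(train, "ppg18"), FAST, "ppg18")
        with pytest.raises(ConfigurationError):
            evaluate_holdout(model, [])

    def test_feature_width_mismatch_rejected(self):
        train = make_subjects(4, 4, seed=14)
        model = train_fcn(build_feature_matrix(train, "ppg18"), FAST, "ppg18")
        gsr_only = build_feature_matrix(train, "gsr24")
        with pytest.raises(ConfigurationError):
            model.predict_proba(gsr_only)
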