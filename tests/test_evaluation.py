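import numpy as np
import pytest

from gaitbalance.classifier import ModelConfig
from gaitbalance.evaluation import (
    DEFAULT_SWEEP_GRIDS, compute_metrics, hyperparameter_sweep,
    joint_ablation, make_loso_folds, run_loso,
)


class TestFolds:
    def test_default_layout_gives_ten_folds_with_published_sizes(
            self, default_dataset):
        folds = make_loso_folds(default_dataset)
        assert len(folds) == 10
        by_subject = {}
        for s in default_dataset:
            by_subject.setdefault(s.subject_id, []).append(s)
        for fold in folds:
            n_train = sum(len(by_subject[s]) for s in fold.train_subjects)
            assert n_train == 240
            assert len(by_subject[fold.val_subject]) == 30
            assert len(by_subject[fold.test_subject]) == 30

    def test_each_subject_tested_exactly_once(self, default_dataset):
        folds = make_loso_folds(default_dataset)
        assert sorted(f.test_subject for f in folds) == list(range(10))

    def test_roles_partition_the_subjects(self, default_dataset):
        subjects = set(default_dataset.subjects)
        for fold in make_loso_folds(default_dataset):
            roles = {fold.test_subject, fold.val_subject, *fold.train_subjects}
            assert roles == subjects
            assert len(roles) == 2 + len(fold.train_subjects)

    def test_fewer_than_three_subjects_rejected(self, small_dataset):
        from gaitbalance.simulator import SimulationConfig, generate_dataset
        two = generate_dataset(SimulationConfig(n_subjects=2, n_trials=1, seed=0))
        with pytest.raises(ValueError, match=">= 3 subjects"):
            make_loso_folds(two)

    def test_random_policy_is_reproducible(self, default_dataset):
        a = make_loso_folds(default_dataset, val_policy="random", seed=3)
        b = make_loso_folds(default_dataset, val_policy="random", seed=3)
        assert a == b


class TestMetrics:
    def test_worked_example(self):
        """Frozen from a hand count of the six predictions."""
        m = compute_metrics([0, 0, 1, 1, 2, 2], [0, 1, 1, 1, 2, 0])
        assert np.isclose(m.accuracy, 4 / 6)
        assert np.isclose(m.macro_precision, (1 / 2 + 2 / 3 + 1) / 3)
        assert np.isclose(m.macro_f1, (0.5 + 0.8 + 2 / 3) / 3)

    def test_perfect_prediction(self):
        m = compute_metrics([0, 1, 2, 1], [0, 1, 2, 1])
        assert m.accuracy == 1.0
        assert m.macro_precision == 1.0
        assert m.macro_f1 == 1.0

    def test_matches_sklearn_on_random_vectors(self):
        """Independent oracle: scikit-learn's macro metrics."""
        from sklearn.metrics import accuracy_score, f1_score, precision_score

        rng = np.random.default_rng(0)
        for _ in range(200):
            yt = rng.integers(0, 3, size=30)
            yp = rng.integers(0, 3, size=30)
            m = compute_metrics(yt, yp)
            assert np.isclose(m.accuracy, accuracy_score(yt, yp))
            assert np.isclose(m.macro_precision,
                              precision_score(yt, yp, average="macro",
                                              zero_division=0))
            assert np.isclose(m.macro_f1,
                              f1_score(yt, yp, average="macro",
                                       zero_division=0))

    def test_confusion_counts_are_consistent(self):
        rng = np.random.default_rng(1)
        yt = rng.integers(0, 3, size=50)
        yp = rng.integers(0, 3, size=50)
        c = compute_metrics(yt, yp).confusion
        assert c.total == 50
        for k in range(3):
            assert c.tp[k] + c.fp[k] + c.tn[k] + c.fn[k] == 50

    def test_never_predicted_class_warns_and_scores_zero(self):
        with pytest.warns(UserWarning, match="never predicted"):
            m = compute_metrics([0, 1, 2], [0, 1, 1])
        assert m.precision[2] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            compute_metrics([0, 1], [0])

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            compute_metrics([0, 3], [0, 1])


class TestLoso:
    @pytest.fixture(scope="class")
    def tiny_report(self, small_dataset):
        cfg = ModelConfig(channels=8, n_blocks=1, max_epochs=6, patience=3,
                          learning_rate=1e-3, dropout_rate=0.2, seed=2)
        return run_loso(small_dataset, "G1", cfg), cfg

    def test_every_sample_tested_exactly_once(self, small_dataset, tiny_report):
        report, _ = tiny_report
        assert len(report.true_labels) == len(small_dataset)

    def test_pooled_accuracy_consistent_with_fold_accuracies(self, tiny_report):
        report, _ = tiny_report
        # equal-size folds: pooled accuracy is the mean of per-fold accuracy
        assert np.isclose(report.metrics.accuracy,
                          np.mean(report.per_fold_accuracy))

    def test_rerun_is_bit_identical(self, small_dataset, tiny_report):
        report, cfg = tiny_report
        again = run_loso(small_dataset, "G1", cfg)
        assert np.array_equal(report.predicted_labels, again.predicted_labels)


class TestAblationAndSweep:
    def test_ablation_requires_control_group(self, small_dataset):
        with pytest.raises(ValueError, match="A0"):
            joint_ablation(small_dataset, ["G1", "G2"])

    def test_ablation_reports_zero_improvement_for_control(self, small_dataset):
        cfg = ModelConfig(channels=4, n_blocks=1, max_epochs=3, patience=2,
                          learning_rate=1e-3, seed=0)
        rep = joint_ablation(small_dataset, ["A0", "G1"], cfg)
        frame = rep.to_frame().set_index("group")
        assert frame.loc["A0", "improvement"] == 0.0
        assert list(frame.index) == ["A0", "G1"]

    def test_default_grids_match_published_tables(self):
        assert len(DEFAULT_SWEEP_GRIDS["kernel_sizes"]) == 64
        assert DEFAULT_SWEEP_GRIDS["channels"] == [4, 8, 16, 32, 64]
        assert DEFAULT_SWEEP_GRIDS["n_blocks"] == [1, 2, 3, 4]
        assert set(DEFAULT_SWEEP_GRIDS["optimizer"]) == {"sgd", "rmsprop", "adam"}

    def test_sweep_records_one_row_per_value_and_finds_best(self, small_dataset):
        cfg = ModelConfig(channels=4, n_blocks=1, max_epochs=3, patience=2,
                          learning_rate=1e-3, seed=0)
        rep = hyperparameter_sweep(small_dataset, "channels", [4, 8], cfg,
                                   group="G1")
        assert len(rep.rows) == 2
        assert rep.best()["val_loss"] == min(r["val_loss"] for r in rep.rows)

    def test_empty_grid_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="non-empty"):
            hyperparameter_sweep(small_dataset, "channels", [])

    def test_unknown_parameter_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="unknown sweep parameter"):
            hyperparameter_sweep(small_dataset, "momentum", [0.9])
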