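"""Classifier, holdout split, and evaluation-metric tests."""

import json

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from somnowave.classify import (
    CHANNEL_COMBINATIONS,
    cohens_kappa,
    evaluate,
    split_holdout,
    train_ebt,
)
from somnowave.features import FeatureTable


def make_table(labels, values=None, scheme=3, seed=0):
    labels = np.asarray(labels, dtype=object)
    if values is None:
        rng = np.random.default_rng(seed)
        # linearly separable: feature 0 encodes the class index
        classes = {c: i for i, c in enumerate(dict.fromkeys(labels))}
        values = np.column_stack(
            [
                np.array([classes[c] for c in labels], dtype=float)
                + rng.uniform(-0.2, 0.2, len(labels)),
                rng.standard_normal(len(labels)),
            ]
        )
    return FeatureTable(
        values=values,
        labels=labels,
        columns=[f"f{i}" for i in range(values.shape[1])],
        channel_set=("EMG",),
        scheme=scheme,
    )


class TestKappa:
    def test_hand_checked_two_by_two(self):
        counts = np.array([[50, 10], [5, 35]])
        # p_o = 0.85, p_e = 0.51 -> kappa = 0.34 / 0.49
        assert cohens_kappa(counts) == pytest.approx(0.34 / 0.49, abs=1e-12)

    def test_matches_sklearn_on_random_tables(self, rng):
        for _ in range(20):
            y_true = rng.integers(0, 3, 200)
            y_pred = rng.integers(0, 3, 200)
            counts = np.zeros((3, 3), dtype=int)
            for t, p in zip(y_true, y_pred):
                counts[t, p] += 1
            assert cohens_kappa(counts) == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12
            )

    def test_degenerate_single_cell_is_zero(self):
        assert cohens_kappa(np.array([[10, 0], [0, 0]])) == 0.0


class TestSplitHoldout:
    def test_sizes(self):
        table = make_table(["W"] * 500 + ["N"] * 300 + ["REM"] * 200)
        train, test = split_holdout(table, 0.10, seed=0)
        assert test.n_epochs == 100
        assert train.n_epochs == 900

    def test_same_seed_same_split(self):
        table = make_table(["W"] * 50 + ["N"] * 50)
        for _ in range(2):
            a = split_holdout(table, 0.10, seed=3)
            b = split_holdout(table, 0.10, seed=3)
            assert np.array_equal(a[0].values, b[0].values)
            assert np.array_equal(a[1].values, b[1].values)

    def test_stratification_preserves_proportions(self):
        table = make_table(["W"] * 900 + ["N"] * 90 + ["REM"] * 10)
        _, test = split_holdout(table, 0.10, seed=1)
        counts = {c: int((test.labels == c).sum()) for c in ("W", "N", "REM")}
        assert abs(counts["W"] - 90) <= 1
        assert abs(counts["N"] - 9) <= 1
        assert abs(counts["REM"] - 1) <= 1

    def test_singleton_class_rejected(self):
        table = make_table(["W"] * 20 + ["REM"])
        with pytest.raises(ValueError, match="single sample"):
            split_holdout(table, 0.10, seed=0)

    def test_bad_fraction_rejected(self):
        table = make_table(["W"] * 10 + ["N"] * 10)
        with pytest.raises(ValueError):
            split_holdout(table, 1.5, seed=0)


class TestTrainEvaluate:
    def test_separable_classes_score_perfectly(self):
        table = make_table(["W"] * 100 + ["N"] * 100, scheme=3)
        train, test = split_holdout(table, 0.10, seed=0)
        model = train_ebt(train, n_trees=10, seed=0)
        report = evaluate(model, test, seed=0)
        assert report.overall_accuracy == 100.0
        assert report.kappa == pytest.approx(1.0)
        # identity row-normalised confusion on the populated rows
        for i, c in enumerate(report.class_order):
            if report.confusion_counts[i].sum():
                assert report.confusion[i, i] == pytest.approx(100.0)

    def test_single_tree_is_valid_ensemble(self):
        table = make_table(["W"] * 60 + ["N"] * 60)
        train, test = split_holdout(table, 0.10, seed=0)
        model = train_ebt(train, n_trees=1, seed=0)
        assert len(model.ensemble.estimators_) == 1
        assert evaluate(model, test).overall_accuracy == 100.0

    def test_memorises_single_point_per_class(self):
        values = np.array([[0.0, 0.0], [1.0, 1.0]] * 5)
        table = make_table(["W", "REM"] * 5, values=values)
        model = train_ebt(table, n_trees=5, seed=0)
        assert model.predict(np.array([[0.0, 0.0]]))[0] == "W"
        assert model.predict(np.array([[1.0, 1.0]]))[0] == "REM"

    def test_all_constant_features_rejected(self):
        values = np.ones((40, 3))
        table = make_table(["W"] * 20 + ["N"] * 20, values=values)
        with pytest.raises(ValueError, match="constant"):
            train_ebt(table, n_trees=3, seed=0)

    def test_single_class_rejected(self):
        table = make_table(["W"] * 30)
        with pytest.raises(ValueError):
            train_ebt(table, n_trees=3, seed=0)

    def test_reports_are_reproducible(self):
        table = make_table(["W"] * 80 + ["N"] * 70 + ["REM"] * 50, seed=5)
        reports = []
        for _ in range(2):
            train, test = split_holdout(table, 0.10, seed=9)
            model = train_ebt(train, n_trees=20, seed=9)
            reports.append(evaluate(model, test, seed=9))
        assert reports[0].to_json() == reports[1].to_json()


class ConstantPredictor:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.array([self.label] * len(X), dtype=object)


class TestEvaluationReport:
    def test_constant_predictor_accuracy_equals_prevalence(self):
        table = make_table(["W"] * 70 + ["N"] * 20 + ["REM"] * 10)
        report = evaluate(ConstantPredictor("W"), table)
        assert report.overall_accuracy == pytest.approx(70.0)
        assert report.kappa == pytest.approx(0.0)

    def test_constant_on_balanced_two_class_is_chance(self):
        table = make_table(["W"] * 50 + ["N"] * 50)
        report = evaluate(ConstantPredictor("W"), table)
        assert report.overall_accuracy == pytest.approx(50.0)
        assert report.kappa == pytest.approx(0.0)

    def test_confusion_rows_sum_to_100(self, small_recording, bank4):
        from somnowave.features import build_feature_table

        table = build_feature_table(small_recording, bank4, scheme=5)
        train, test = split_holdout(table, 0.10, seed=0)
        model = train_ebt(train, n_trees=10, seed=0)
        report = evaluate(model, test)
        sums = report.confusion.sum(axis=1)
        for i in range(len(report.class_order)):
            if report.confusion_counts[i].sum():
                assert sums[i] == pytest.approx(100.0, abs=0.5)

    def test_kappa_consistent_with_own_counts(self, small_recording, bank4):
        from somnowave.features import build_feature_table

        table = build_feature_table(small_recording, bank4, scheme=3)
        train, test = split_holdout(table, 0.10, seed=0)
        model = train_ebt(train, n_trees=10, seed=0)
        report = evaluate(model, test)
        assert report.kappa == pytest.approx(
            cohens_kappa(report.confusion_counts), abs=1e-12
        )

    def test_json_is_parseable(self):
        table = make_table(["W"] * 40 + ["N"] * 40)
        train, test = split_holdout(table, 0.10, seed=0)
        model = train_ebt(train, n_trees=5, seed=0)
        payload = json.loads(evaluate(model, test).to_json())
        assert payload["holdout_fraction"] == 0.10
        assert len(payload["confusion_percent"]) == len(payload["class_order"])


class TestChannelCombinations:
    def test_fifteen_combinations_with_all_singletons(self):
        assert len(CHANNEL_COMBINATIONS) == 15
        singles = {c[0] for c in CHANNEL_COMBINATIONS if len(c) == 1}
        assert singles == {"EMG", "EOG-R", "EOG-L", "C4-A1", "C3-A2"}
        assert CHANNEL_COMBINATIONS[-1] == (
            "C3-A2", "C4-A1", "EMG", "EOG-R", "EOG-L",
        )
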