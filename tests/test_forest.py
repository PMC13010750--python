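"""Random Forest pipeline: splits, training, metrics, grid search, comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from audiosem.errors import ConfigurationError
from audiosem.forest import (
    DEFAULT_GRID,
    ForestSpec,
    compare_strategies,
    cross_validate,
    evaluate,
    feature_importances,
    grid_search,
    log_loss_score,
    stratified_split,
    train_forest,
)


@pytest.fixture(scope="module")
def separable():
    """Two linearly separable classes in two features."""
    rng = np.random.default_rng(1)
    X = pd.DataFrame({
        "x0": np.concatenate([rng.normal(-5, 0.5, 60), rng.normal(5, 0.5, 60)]),
        "x1": rng.normal(0, 1, 120),
    })
    y = np.array(["neg"] * 60 + ["pos"] * 60, dtype=object)
    return X, y


class TestStratifiedSplit:
    def test_exact_per_class_counts(self):
        y = np.repeat(["a", "b", "c", "d"], 25)
        train_idx, test_idx = stratified_split(y, 0.2, seed=0)
        assert len(train_idx) == 80 and len(test_idx) == 20
        assert not set(train_idx) & set(test_idx)
        test_counts = pd.Series(y[test_idx]).value_counts()
        assert (test_counts == 5).all()

    def test_half_split_two_by_two(self):
        y = np.array(["a", "a", "b", "b"])
        train_idx, test_idx = stratified_split(y, 0.5, seed=0)
        assert sorted(y[train_idx]) == ["a", "b"]
        assert sorted(y[test_idx]) == ["a", "b"]

    def test_seed_determinism(self):
        y = np.repeat(["a", "b"], 30)
        assert np.array_equal(stratified_split(y, 0.2, 5)[1], stratified_split(y, 0.2, 5)[1])

    def test_singleton_class_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_split(np.array(["a", "a", "b"]), 0.5, 0)


class TestTrainForest:
    def test_separable_training_accuracy_is_one(self, separable):
        X, y = separable
        model = train_forest(X, y, ForestSpec(n_estimators=50, seed=0))
        assert (model.predict(X) == y).all()

    def test_stump_has_at_most_two_probability_vectors(self, separable):
        X, y = separable
        model = train_forest(X, y, ForestSpec(n_estimators=1, max_depth=1, seed=0))
        proba = model.predict_proba(X)
        assert len(np.unique(proba.round(12), axis=0)) <= 2

    def test_seed_determinism(self, separable):
        X, y = separable
        a = train_forest(X, y, ForestSpec(n_estimators=20, seed=7)).predict_proba(X)
        b = train_forest(X, y, ForestSpec(n_estimators=20, seed=7)).predict_proba(X)
        assert np.array_equal(a, b)


class TestLogLoss:
    def test_perfect_prediction_is_zero(self):
        proba = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert log_loss_score(["a", "b"], proba, ("a", "b")) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_four_class_is_ln4(self):
        proba = np.full((10, 4), 0.25)
        y = np.array(list("abcd") * 2 + ["a", "b"], dtype=object)
        value = log_loss_score(y, proba, ("a", "b", "c", "d"))
        assert value == pytest.approx(math.log(4), rel=1e-12)


class TestEvaluate:
    def test_metrics_match_hand_computed_confusion(self, separable):
        """Confusion matrix [[8,2],[1,9]]: precision 8/9, recall 0.8, F1 ~ 0.842."""
        X, _ = separable
        y_true = np.array(["a"] * 10 + ["b"] * 10, dtype=object)
        y_pred = np.array(["a"] * 8 + ["b"] * 2 + ["a"] * 1 + ["b"] * 9, dtype=object)
        from sklearn.metrics import precision_recall_fscore_support

        prec, rec, f1, _ = precision_recall_fscore_support(y_true, y_pred, labels=["a", "b"])
        assert prec[0] == pytest.approx(8 / 9)
        assert rec[0] == pytest.approx(0.8)
        assert f1[0] == pytest.approx(2 * (8 / 9) * 0.8 / (8 / 9 + 0.8))

    def test_report_fields_on_fitted_model(self, separable):
        X, y = separable
        train_idx, test_idx = stratified_split(y, 0.2, seed=0)
        model = train_forest(X.iloc[train_idx], y[train_idx], ForestSpec(n_estimators=50, seed=0))
        report = evaluate(model, X.iloc[test_idx], y[test_idx])
        assert report.accuracy == 1.0
        assert report.log_loss < 0.1
        assert report.confusion.sum() == len(test_idx)
        assert report.confusion.sum(axis=1).tolist() == [report.support[c] for c in report.class_order]


class TestCrossValidate:
    def test_learnable_labels_score_near_one(self, separable):
        X, y = separable
        mean, std = cross_validate(X, y, ForestSpec(n_estimators=30, seed=0), folds=5, seed=0)
        assert mean > 0.99 and std < 0.05

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(400, 5)), columns=list("abcde"))
        y = np.array(list("wxyz") * 100, dtype=object)
        rng.shuffle(y)
        mean, _ = cross_validate(X, y, ForestSpec(n_estimators=40, seed=0), folds=5, seed=0)
        assert abs(mean - 0.25) < 0.08

    def test_class_smaller_than_folds_rejected(self, separable):
        X, _ = separable
        y = np.array(["a"] * 117 + ["b"] * 3, dtype=object)
        with pytest.raises(ConfigurationError):
            cross_validate(X, y, ForestSpec(), folds=5, seed=0)


class TestGridSearch:
    def test_one_point_grid_returned(self, separable):
        X, y = separable
        spec, table = grid_search(X, y, {"n_estimators": [10]}, folds=3, seed=0)
        assert spec.n_estimators == 10 and len(table) == 1

    def test_tie_break_prefers_smaller_model(self, separable):
        X, y = separable  # perfectly separable: every spec scores 1.0
        spec, table = grid_search(
            X, y, {"n_estimators": [50, 10], "max_depth": [30, 10]}, folds=3, seed=0
        )
        assert (spec.n_estimators, spec.max_depth) == (10, 10)
        assert len(table) == 4

    def test_default_grid_covers_tested_ranges(self):
        assert DEFAULT_GRID["n_estimators"] == [100, 200, 300, 400, 500]
        assert DEFAULT_GRID["max_depth"] == [10, 20, 30, 40, 50]
        assert DEFAULT_GRID["min_samples_split"] == [2, 5, 10, 20]
        assert DEFAULT_GRID["max_features"] == ["sqrt", "log2"]

    def test_empty_grid_rejected(self, separable):
        X, y = separable
        with pytest.raises(ConfigurationError):
            grid_search(X, y, {}, folds=3, seed=0)


class TestFeatureImportances:
    def test_normalized_and_constant_feature_zero(self, separable):
        X, y = separable
        X = X.assign(const=1.0)
        model = train_forest(X, y, ForestSpec(n_estimators=30, seed=0))
        weights = feature_importances(model)
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert weights["const"] == 0.0
        assert list(weights.values()) == sorted(weights.values(), reverse=True)

    def test_threshold_features_dominate_comorbidity_flags(self, config, rule_base, noisy_cohort):
        """Labels depend only on audiometry, so every comorbidity-flag weight
        sits below every threshold weight that the trees actually used."""
        from audiosem.features import feature_frame
        from audiosem.rules import apply_rule_base

        records, _ = noisy_cohort
        X = feature_frame(records, config)
        y = np.array([apply_rule_base(r, rule_base, config).hl_type for r in records], dtype=object)
        model = train_forest(X, y, ForestSpec(n_estimators=100, seed=0))
        weights = feature_importances(model)
        flag_max = max(weights[f] for f in
                       ("diabetes", "hypertension", "cardiovascular",
                        "noise_exposure", "smoking", "alcohol"))
        used_thresholds = [w for n, w in weights.items() if "_air_" in n and w > 0.01]
        assert used_thresholds and min(used_thresholds) > flag_max

    def test_unfitted_model_rejected(self):
        with pytest.raises(ConfigurationError):
            feature_importances(ForestSpec(n_estimators=5).build())


@pytest.fixture(scope="module")
def report(noisy_cohort, config):
    records, _ = noisy_cohort
    return compare_strategies(records, config, seed=7,
                              spec=ForestSpec(n_estimators=50, seed=7))


class TestCompareStrategies:
    def test_table_has_exact_rows_and_columns(self, report):
        assert list(report.table.index) == [
            "test_accuracy_pct", "cv_mean_accuracy_pct", "cv_std_accuracy_pct",
            "f1_sensorineural", "f1_conductive", "f1_mixed", "f1_normal",
            "log_loss",
        ]
        assert list(report.table.columns) == ["rf_kmeans", "rf_ontology"]

    def test_same_seed_reproduces_report(self, noisy_cohort, config, report):
        records, _ = noisy_cohort
        again = compare_strategies(records, config, seed=7,
                                   spec=ForestSpec(n_estimators=50, seed=7))
        pd.testing.assert_frame_equal(report.table, again.table)

    def test_anti_leakage_feature_sets(self, report):
        onto_features = set(report.ontology.feature_importances)
        assert {"sem_severity", "sem_laterality"} <= onto_features
        assert "sem_type" not in onto_features and "sem_treatment" not in onto_features
        assert "sem_severity" not in report.kmeans.feature_importances
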