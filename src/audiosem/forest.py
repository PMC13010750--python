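"""Random Forest training, evaluation and strategy comparison.

Trains Random Forest classifiers on either labeling strategy (K-Means cluster
labels vs rule-engine semantic labels) and produces the side-by-side
comparison report: test accuracy, 5-fold cross-validation mean/std, per-class
F1 and log loss for both arms.

Anti-leakage contract: a prediction target's own label column never appears
in its feature set.  For the headline type task the ontology arm's semantic
features are the severity and laterality labels only; the type and treatment
labels are used exclusively as supervised targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product as _product
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, train_test_split

from .clustering import kmeans_label_cohort
from .errors import ConfigurationError, SchemaError
from .features import FeatureConfig, PatientRecord, feature_frame
from .rules import RuleBase, SemanticLabels, apply_rule_base, default_rule_base
from .vocab import HL_TYPES

logger = logging.getLogger(__name__)

LOG_LOSS_EPS = 1e-15


@dataclass(frozen=True)
class ForestSpec:
    """Random Forest hyperparameters (defaults sit mid-range of the grid)."""

    n_estimators: int = 300
    max_depth: Optional[int] = None
    min_samples_split: int = 2
    max_features: Union[str, float] = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ConfigurationError("n_estimators must be >= 1")
        if self.min_samples_split < 2:
            raise ConfigurationError("min_samples_split must be >= 2")

    def build(self) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            max_features=self.max_features,
            random_state=self.seed,
            n_jobs=1,
        )


@dataclass
class MetricsReport:
    """Evaluation metrics for one fitted model on one test set."""

    accuracy: float
    precision: Dict[str, float]
    recall: Dict[str, float]
    f1: Dict[str, float]
    support: Dict[str, int]
    log_loss: float
    confusion: np.ndarray
    class_order: Tuple[str, ...]
    cv_mean: Optional[float] = None
    cv_std: Optional[float] = None
    feature_importances: Dict[str, float] = field(default_factory=dict)


def stratified_split(labels: Sequence, test_fraction: float = 0.2,
                     seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint, covering train/test index sets with per-class proportions
    preserved to within one record."""
    y = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError("test_fraction must lie strictly in (0, 1)")
    classes, counts = np.unique(y, return_counts=True)
    singletons = classes[counts < 2]
    if len(singletons):
        raise ConfigurationError(
            f"cannot stratify: class(es) {list(singletons)} have fewer than 2 members"
        )
    train_idx, test_idx = train_test_split(
        np.arange(len(y)), test_size=test_fraction, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


def train_forest(X: pd.DataFrame, y: Sequence, spec: ForestSpec) -> RandomForestClassifier:
    """Fit the bagged tree ensemble described by ``spec``."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ConfigurationError("empty training set")
    model = spec.build()
    model.fit(X, y)
    return model


def log_loss_score(y_true: Sequence, proba: np.ndarray,
                   class_order: Sequence[str], eps: float = LOG_LOSS_EPS) -> float:
    """Mean negative log-likelihood of the true class, probabilities clipped
    to ``[eps, 1-eps]``; 0 for perfect confident prediction, ln C for uniform
    guessing over C classes."""
    y_true = np.asarray(y_true)
    proba = np.clip(np.asarray(proba, dtype=float), eps, 1.0 - eps)
    index = {c: i for i, c in enumerate(class_order)}
    picks = proba[np.arange(len(y_true)), [index[v] for v in y_true]]
    return float(-np.mean(np.log(picks)))


def evaluate(model: RandomForestClassifier, X_test: pd.DataFrame,
             y_test: Sequence) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1, confusion matrix and log loss."""
    if len(X_test) == 0:
        raise ConfigurationError("empty test set")
    if list(X_test.columns) != list(model.feature_names_in_):
        raise SchemaError("test feature schema differs from the training schema")
    y_test = np.asarray(y_test)
    y_pred = model.predict(X_test)
    classes = tuple(model.classes_)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_test, y_pred, labels=list(classes), zero_division=0
    )
    return MetricsReport(
        accuracy=float(accuracy_score(y_test, y_pred)),
        precision=dict(zip(classes, map(float, prec))),
        recall=dict(zip(classes, map(float, rec))),
        f1=dict(zip(classes, map(float, f1))),
        support=dict(zip(classes, map(int, support))),
        log_loss=log_loss_score(y_test, model.predict_proba(X_test), classes),
        confusion=confusion_matrix(y_test, y_pred, labels=list(classes)),
        class_order=classes,
    )


def cross_validate(X: pd.DataFrame, y: Sequence, spec: ForestSpec,
                   folds: int = 5, seed: int = 0) -> Tuple[float, float]:
    """Stratified k-fold accuracy: (mean, population standard deviation)."""
    y = np.asarray(y)
    if folds < 2:
        raise ConfigurationError("folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ConfigurationError(
            f"every class needs >= {folds} members for {folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(X, y):
        model = train_forest(X.iloc[train_idx], y[train_idx], spec)
        scores.append(accuracy_score(y[test_idx], model.predict(X.iloc[test_idx])))
    scores = np.asarray(scores)
    return float(scores.mean()), float(scores.std())  # ddof=0: population std


#: hyperparameter grid mirroring the tested ranges.
DEFAULT_GRID = {
    "n_estimators": [100, 200, 300, 400, 500],
    "max_depth": [10, 20, 30, 40, 50],
    "min_samples_split": [2, 5, 10, 20],
    "max_features": ["sqrt", "log2"],
}


def grid_search(X: pd.DataFrame, y: Sequence, grid: Dict[str, list],
                folds: int = 5, seed: int = 0) -> Tuple[ForestSpec, pd.DataFrame]:
    """Exhaustive grid search by stratified k-fold CV accuracy.

    Ties are broken toward the smaller model: fewer trees, then shallower
    depth.  Returns the winning spec and the full score table.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("empty hyperparameter grid")
    keys = sorted(grid)
    rows = []
    for combo in _product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        spec = ForestSpec(seed=seed, **params)
        mean, std = cross_validate(X, y, spec, folds=folds, seed=seed)
        rows.append({**params, "cv_mean": mean, "cv_std": std})
    table = pd.DataFrame(rows)
    depth_key = table["max_depth"].map(lambda d: np.inf if d is None else d) \
        if "max_depth" in table.columns else pd.Series(0, index=table.index)
    trees_key = table.get("n_estimators", pd.Series(0, index=table.index))
    order = sorted(
        table.index,
        key=lambda i: (-table.loc[i, "cv_mean"], trees_key[i], depth_key[i]),
    )
    best = table.loc[order[0]]
    spec = ForestSpec(seed=seed, **{k: best[k] for k in keys})
    return spec, table


def feature_importances(model: RandomForestClassifier,
                        feature_names: Optional[Sequence[str]] = None) -> Dict[str, float]:
    """Mean impurity-decrease weights, normalized to sum 1, descending."""
    try:
        raw = model.feature_importances_
    except Exception as exc:
        raise ConfigurationError("model is not fitted") from exc
    names = list(feature_names) if feature_names is not None else list(model.feature_names_in_)
    total = raw.sum()
    weights = raw / total if total > 0 else raw
    pairs = sorted(zip(names, map(float, weights)), key=lambda p: -p[1])
    return dict(pairs)


# ---------------------------------------------------------------------------
# the two-arm comparison (Table-4-analog report)
# ---------------------------------------------------------------------------

TABLE_ROWS = (
    "test_accuracy_pct",
    "cv_mean_accuracy_pct",
    "cv_std_accuracy_pct",
    "f1_sensorineural",
    "f1_conductive",
    "f1_mixed",
    "f1_normal",
    "log_loss",
)


@dataclass
class ComparisonReport:
    """Side-by-side metrics for the K-Means and ontology-enriched arms."""

    kmeans: MetricsReport
    ontology: MetricsReport
    table: pd.DataFrame
    seed: int

    def write_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.6f")


def _arm_report(X: pd.DataFrame, y: np.ndarray, spec: ForestSpec, folds: int,
                seed: int, arm: str) -> MetricsReport:
    train_idx, test_idx = stratified_split(y, 0.2, seed=seed)
    model = train_forest(X.iloc[train_idx], y[train_idx], spec)
    report = evaluate(model, X.iloc[test_idx], y[test_idx])
    report.cv_mean, report.cv_std = cross_validate(X, y, spec, folds=folds, seed=seed)
    report.feature_importances = feature_importances(model, list(X.columns))
    logger.info("%s arm: test accuracy %.4f, CV %.4f +/- %.4f, log loss %.4f",
                arm, report.accuracy, report.cv_mean, report.cv_std, report.log_loss)
    return report


def _table_column(report: MetricsReport) -> List[float]:
    f1s = [report.f1.get(c, float("nan"))
           for c in ("sensorineural", "conductive", "mixed", "normal")]
    return [report.accuracy * 100.0, report.cv_mean * 100.0,
            report.cv_std * 100.0, *f1s, report.log_loss]


def compare_strategies(records: Sequence[PatientRecord],
                       config: Optional[FeatureConfig] = None,
                       seed: int = 0,
                       spec: Optional[ForestSpec] = None,
                       folds: int = 5,
                       rules: Optional[RuleBase] = None,
                       semantic_labels: Optional[Sequence[SemanticLabels]] = None,
                       ) -> ComparisonReport:
    """Run the full pipeline twice and emit the side-by-side report.

    Arm (a): K-Means type labels as targets, raw features only.
    Arm (b): rule-engine type labels as targets, features enriched with the
    semantic severity and laterality labels (anti-circularity: the type and
    treatment labels themselves never enter the feature set).
    """
    config = config or FeatureConfig()
    rules = rules or default_rule_base(config)
    spec = spec or ForestSpec(seed=seed)
    if spec.seed != seed:
        spec = replace(spec, seed=seed)

    sem = (list(semantic_labels) if semantic_labels is not None
           else [apply_rule_base(r, rules, config) for r in records])
    y_onto = np.array([s.hl_type for s in sem], dtype=object)
    X_onto = feature_frame(records, config, semantic=sem,
                           semantic_fields=("severity", "laterality"))
    X_raw = feature_frame(records, config)
    km_table = kmeans_label_cohort(records, config, seed=seed, reference=sem)
    y_km = km_table["kmeans_type"].to_numpy(dtype=object)

    km_report = _arm_report(X_raw, y_km, spec, folds, seed, "kmeans")
    onto_report = _arm_report(X_onto, y_onto, spec, folds, seed, "ontology")

    table = pd.DataFrame(
        {"rf_kmeans": _table_column(km_report),
         "rf_ontology": _table_column(onto_report)},
        index=list(TABLE_ROWS),
    )
    table.index.name = "metric"
    return ComparisonReport(kmeans=km_report, ontology=onto_report,
                            table=table, seed=seed)
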