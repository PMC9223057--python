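"""Ensemble bagged-tree sleep staging and its evaluation.

Features are classified with bootstrap-aggregated decision trees (bagging:
each tree is grown on a with-replacement resample of the training set of
the same size; prediction is by majority vote with ties broken toward the
more prevalent training class).  Evaluation follows the conventions of the
sleep-staging literature: a single stratified 10% holdout split, overall
accuracy, per-class accuracy (recall per true stage), Cohen's kappa, and a
row-normalised confusion matrix, repeated over the fifteen standard
channel combinations of the five-channel montage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable, build_feature_table
from .psg_io import STAGES_3, STAGES_5

__all__ = [
    "EvaluationReport",
    "EBTModel",
    "split_holdout",
    "train_ebt",
    "evaluate",
    "channel_sweep",
    "CHANNEL_COMBINATIONS",
    "cohens_kappa",
    "DEFAULT_N_TREES",
    "HOLDOUT_FRACTION",
]

DEFAULT_N_TREES = 30
HOLDOUT_FRACTION = 0.10

# The fifteen channel combinations reported for the five-channel montage:
# every singleton, both EEGs, EMG/EOG pairs and triple, and the EEG-anchored
# combinations up to the full montage.
CHANNEL_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("EMG",),
    ("EOG-R",),
    ("EOG-L",),
    ("C4-A1",),
    ("C3-A2",),
    ("C4-A1", "C3-A2"),
    ("EMG", "EOG-R"),
    ("EMG", "EOG-L"),
    ("EOG-R", "EOG-L"),
    ("EMG", "EOG-R", "EOG-L"),
    ("C3-A2", "C4-A1", "EMG"),
    ("C3-A2", "C4-A1", "EOG-R", "EOG-L"),
    ("C3-A2", "C4-A1", "EMG", "EOG-R"),
    ("C3-A2", "C4-A1", "EMG", "EOG-L"),
    ("C3-A2", "C4-A1", "EMG", "EOG-R", "EOG-L"),
)


def _class_order(scheme: int) -> tuple[str, ...]:
    return STAGES_3 if scheme == 3 else STAGES_5


@dataclass
class EvaluationReport:
    """Holdout evaluation of one channel combination and class scheme."""

    scheme: int
    channel_set: tuple[str, ...]
    class_order: tuple[str, ...]
    overall_accuracy: float  # percent
    per_class_accuracy: dict[str, float]  # percent, recall per true class
    kappa: float
    confusion: np.ndarray  # row-normalised, percent
    confusion_counts: np.ndarray
    holdout_fraction: float
    seed: int
    n_test: int

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "channel_set": list(self.channel_set),
            "class_order": list(self.class_order),
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "kappa": self.kappa,
            "confusion_percent": self.confusion.tolist(),
            "confusion_counts": self.confusion_counts.tolist(),
            "holdout_fraction": self.holdout_fraction,
            "seed": self.seed,
            "n_test": self.n_test,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def cohens_kappa(counts: np.ndarray) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e) from a confusion-count matrix.

    p_e is the chance agreement from the marginal products; kappa is defined
    as 0 when p_e = 1 (degenerate single-cell table).
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) / total) @ (counts.sum(axis=0) / total))
    if abs(1.0 - p_e) < 1e-15:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def split_holdout(
    table: FeatureTable,
    fraction: float = HOLDOUT_FRACTION,
    seed: int = 0,
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified random train/test split of the feature table."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"holdout fraction must lie in (0, 1), got {fraction}")
    classes, counts = np.unique(table.labels, return_counts=True)
    singletons = classes[counts < 2]
    if len(singletons):
        raise ValueError(
            f"class(es) {list(singletons)} have a single sample; cannot "
            "stratify a holdout split"
        )
    idx_train, idx_test = train_test_split(
        np.arange(table.n_epochs),
        test_size=fraction,
        random_state=seed,
        stratify=table.labels,
    )

    def subset(idx: np.ndarray) -> FeatureTable:
        return FeatureTable(
            values=table.values[idx],
            labels=table.labels[idx],
            columns=table.columns,
            channel_set=table.channel_set,
            scheme=table.scheme,
        )

    return subset(idx_train), subset(idx_test)


@dataclass
class EBTModel:
    """Bagged decision-tree ensemble with prevalence-aware tie-breaking."""

    ensemble: BaggingClassifier
    classes_: np.ndarray
    prevalence_: np.ndarray  # training prevalence per class
    n_trees: int
    seed: int
    feature_columns: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.ensemble.predict_proba(np.asarray(X, dtype=float))
        # argmax with ties going to the more prevalent training class
        out = np.empty(len(proba), dtype=object)
        for i, row in enumerate(proba):
            best = row.max()
            tied = np.flatnonzero(row >= best - 1e-12)
            out[i] = self.classes_[tied[np.argmax(self.prevalence_[tied])]]
        return out


def train_ebt(
    train: FeatureTable,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> EBTModel:
    """Train the bagged decision-tree ensemble on a feature table."""
    X, y = train.values, train.labels.astype(str)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if np.all(X == X[0:1, :]):
        raise ValueError("all feature columns are constant; nothing to learn")
    ensemble = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_trees,
        bootstrap=True,
        max_samples=1.0,
        random_state=seed,
    )
    ensemble.fit(X, y)
    prevalence = np.array([(y == c).mean() for c in ensemble.classes_])
    return EBTModel(
        ensemble=ensemble,
        classes_=ensemble.classes_,
        prevalence_=prevalence,
        n_trees=n_trees,
        seed=seed,
        feature_columns=list(train.columns),
    )


def evaluate(model: EBTModel, test: FeatureTable, seed: int = 0) -> EvaluationReport:
    """Evaluate a trained model on held-out epochs."""
    if test.n_epochs == 0:
        raise ValueError("empty test set")
    order = _class_order(test.scheme)
    unknown = set(test.labels.astype(str)) - set(order)
    if unknown:
        raise ValueError(f"test labels {sorted(unknown)} not in scheme {test.scheme}")
    y_true = test.labels.astype(str)
    y_pred = model.predict(test.values).astype(str)
    counts = confusion_matrix(y_true, y_pred, labels=list(order))
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = np.where(
            row_sums[:, None] > 0, 100.0 * counts / row_sums[:, None], 0.0
        )
    per_class = {
        c: (100.0 * counts[i, i] / row_sums[i] if row_sums[i] else float("nan"))
        for i, c in enumerate(order)
    }
    return EvaluationReport(
        scheme=test.scheme,
        channel_set=test.channel_set,
        class_order=order,
        overall_accuracy=100.0 * np.trace(counts) / counts.sum(),
        per_class_accuracy=per_class,
        kappa=cohens_kappa(counts),
        confusion=confusion,
        confusion_counts=counts,
        holdout_fraction=HOLDOUT_FRACTION,
        seed=seed,
        n_test=test.n_epochs,
    )


def channel_sweep(
    epochs,
    bank,
    scheme: int,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
    features: FeatureTable | None = None,
) -> list[EvaluationReport]:
    """Train/evaluate the fifteen standard channel combinations.

    All combinations share the same split seed so their holdout epochs
    coincide.  A precomputed full-montage ``features`` table may be passed
    to avoid recomputing the decomposition.
    """
    if features is None:
        channels = tuple(sorted({c for combo in CHANNEL_COMBINATIONS for c in combo}))
        features = build_feature_table(epochs, bank, channels, scheme=scheme)
    reports = []
    for combo in CHANNEL_COMBINATIONS:
        sub = features.select_channels(combo)
        train, test = split_holdout(sub, HOLDOUT_FRACTION, seed)
        model = train_ebt(train, n_trees=n_trees, seed=seed)
        reports.append(evaluate(model, test, seed=seed))
    return reports
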