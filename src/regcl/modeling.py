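"""Classifier training and evaluation on TFBS-cluster feature matrices.

The primary learner is an unpruned CART decision tree with Gini impurity
(axis-aligned binary splits, grown until leaves are pure or unsplittable);
naive Bayes, random forest and SVMs with four kernels are available for
comparison.  Evaluation follows the published protocol: 10 rounds of
stratified 10-fold cross-validation with freshly drawn folds per round,
reporting sensitivity, specificity and accuracy per round and their means,
plus ROC/AUC and Gini feature importances for tree-based learners.

Scores for ROC from a hard tree are the positive-class fraction at the leaf
(``predict_proba``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .featurization import FeatureMatrix

__all__ = ["TrainedModel", "EvalReport", "train", "cross_validate", "roc_auc",
           "gini_importance", "KINDS"]

KINDS = (
    "decision_tree",
    "naive_bayes",
    "random_forest",
    "svm_linear",
    "svm_rbf",
    "svm_poly",
    "svm_sigmoid",
)


def _make_estimator(kind: str, seed: int):
    if kind == "decision_tree":
        # CART, Gini impurity, unpruned: the re-specified "default" tree
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if kind.startswith("svm_"):
        kernel = kind.removeprefix("svm_")
        if kernel not in ("linear", "rbf", "poly", "sigmoid"):
            raise ValueError(f"unknown SVM kernel {kernel!r}")
        return SVC(kernel=kernel, random_state=seed)
    raise ValueError(f"unknown learner kind {kind!r}; choose from {KINDS}")


def _as_array(X) -> tuple[np.ndarray, FeatureMatrix | None]:
    if isinstance(X, FeatureMatrix):
        return X.X, X
    return np.asarray(X, dtype=float), None


def _check_labels(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")


@dataclass
class TrainedModel:
    """A fitted classifier plus the column schema it was trained under."""

    kind: str
    estimator: object
    schema: list | None = None
    m_max: int | None = None
    mode: str | None = None
    panel: list | None = None

    def predict(self, X) -> np.ndarray:
        arr, _ = _as_array(X)
        return np.asarray(self.estimator.predict(arr))

    def predict_score(self, X) -> np.ndarray:
        """Positive-class score in [0, 1].

        Tree/forest/NB: positive-class probability (leaf class fraction for a
        hard tree).  Margin classifiers without probabilities: the decision
        function min-max scaled into [0, 1] (rank-preserving, so ROC/AUC are
        unaffected).
        """
        arr, _ = _as_array(X)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return np.asarray(est.predict_proba(arr))[:, 1]
        scores = np.asarray(est.decision_function(arr), dtype=float)
        lo, hi = scores.min(), scores.max()
        return (scores - lo) / (hi - lo) if hi > lo else np.full_like(scores, 0.5)


def train(X, y, kind: str = "decision_tree", seed: int = 0) -> TrainedModel:
    """Fit a classifier; deterministic under a fixed seed."""
    arr, fm = _as_array(X)
    y = np.asarray(y)
    _check_labels(y)
    est = _make_estimator(kind, seed)
    est.fit(arr, y)
    return TrainedModel(
        kind=kind,
        estimator=est,
        schema=fm.schema if fm else None,
        m_max=fm.m_max if fm else None,
        mode=fm.mode if fm else None,
        panel=fm.panel if fm else None,
    )


@dataclass
class EvalReport:
    """Cross-validation metrics: one row per round plus their means."""

    kind: str
    rounds: list[dict] = field(default_factory=list)

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean([r["sensitivity"] for r in self.rounds]))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean([r["specificity"] for r in self.rounds]))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r["accuracy"] for r in self.rounds]))


def cross_validate(
    X,
    y,
    rounds: int = 10,
    folds: int = 10,
    kind: str = "decision_tree",
    seed: int = 0,
) -> EvalReport:
    """``rounds`` repetitions of stratified ``folds``-fold cross-validation.

    Folds are re-drawn each round from a seeded stream.  Per round, the
    confusion counts are accumulated over the test folds; sensitivity is
    TP/(TP+FN) on the positive (1) class, specificity TN/(TN+FP).
    """
    arr, _ = _as_array(X)
    y = np.asarray(y)
    _check_labels(y)
    if len(y) < folds:
        raise ValueError(f"n={len(y)} < folds={folds}")
    ss = np.random.SeedSequence(seed)
    round_seeds = ss.generate_state(rounds + 1)
    report = EvalReport(kind=kind)
    for r in range(rounds):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(round_seeds[r] % (2**31 - 1))
        )
        tp = tn = fp = fn = 0
        for train_idx, test_idx in skf.split(arr, y):
            est = _make_estimator(kind, int(round_seeds[-1] % (2**31 - 1)))
            est.fit(arr[train_idx], y[train_idx])
            pred = est.predict(arr[test_idx])
            truth = y[test_idx]
            tp += int(np.sum((pred == 1) & (truth == 1)))
            tn += int(np.sum((pred == 0) & (truth == 0)))
            fp += int(np.sum((pred == 1) & (truth == 0)))
            fn += int(np.sum((pred == 0) & (truth == 1)))
        report.rounds.append(
            {
                "round": r,
                "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
                "specificity": tn / (tn + fp) if tn + fp else float("nan"),
                "accuracy": (tp + tn) / (tp + tn + fp + fn),
            }
        )
    return report


def roc_auc(model: TrainedModel, X, y) -> tuple[np.ndarray, float]:
    """ROC curve (rows of fpr, tpr) and trapezoidal AUC from model scores."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined for single-class labels")
    scores = model.predict_score(X)
    fpr, tpr, _ = roc_curve(y, scores)
    return np.column_stack([fpr, tpr]), float(_auc(fpr, tpr))


def gini_importance(model: TrainedModel) -> np.ndarray:
    """Per-feature Gini (impurity-decrease) importances, summing to 1.

    Zero for unused features; all-zero when the tree made no split.
    """
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise ValueError(f"{model.kind} does not expose Gini importances")
    return np.asarray(est.feature_importances_, dtype=float).copy()
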