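"""Confusion-based metrics, ROC/AUC, and stratified k-fold cross-validation.

With the druggable class as positive (label 1):

* ACC = (tp + tn) / (tp + tn + fp + fn)
* SEN = tp / (tp + fn)
* SPE = tn / (tn + fp)
* MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)), 0 when the
  denominator vanishes (standard convention).

AUC is the threshold-free Mann-Whitney statistic: the probability that a
random positive outscores a random negative, ties counted 1/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .nqlc import fit_standardization, standardize

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion_from_predictions",
    "metrics",
    "roc_auc",
    "roc_points",
    "EvaluationReport",
    "stratified_kfold_cv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


class Metrics(NamedTuple):
    acc: float
    sen: float
    spe: float
    mcc: float


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must align")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """ACC, SEN, SPE and MCC of a confusion table.

    SEN (SPE) is 0 when no positives (negatives) were evaluated; MCC is 0
    when its denominator vanishes. All-zero counts are an error.
    """
    if c.n == 0:
        raise ValueError("empty confusion table")
    acc = (c.tp + c.tn) / c.n
    sen = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    spe = c.tn / (c.tn + c.fp) if c.tn + c.fp else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom) if denom else 0.0
    return Metrics(float(acc), float(sen), float(spe), float(mcc))


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC of positive-class scores; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, labels) -> np.ndarray:
    """(FPR, TPR, threshold) triples of the empirical ROC curve."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thr])


@dataclass
class EvaluationReport:
    """Per-fold and aggregated cross-validation results."""

    k: int
    seed: int
    fold_confusions: list = field(default_factory=list)
    fold_metrics: list = field(default_factory=list)
    fold_assignment: np.ndarray | None = None
    auc: float = float("nan")

    @property
    def pooled_confusion(self) -> ConfusionCounts:
        total = ConfusionCounts(0, 0, 0, 0)
        for c in self.fold_confusions:
            total = total + c
        return total

    @property
    def mean_metrics(self) -> Metrics:
        arr = np.array(self.fold_metrics)
        return Metrics(*arr.mean(axis=0))

    @property
    def pooled_metrics(self) -> Metrics:
        return metrics(self.pooled_confusion)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "auc": self.auc,
            "mean": self.mean_metrics._asdict(),
            "pooled": self.pooled_metrics._asdict(),
            "folds": [
                {"confusion": vars(c), **m._asdict()}
                for c, m in zip(self.fold_confusions, self.fold_metrics)
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        m = self.mean_metrics
        return (
            f"{self.k}-fold CV (seed {self.seed}): "
            f"ACC={m.acc:.4f} SEN={m.sen:.4f} SPE={m.spe:.4f} "
            f"MCC={m.mcc:.4f} AUC={self.auc:.4f}"
        )


def stratified_kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    model_factory: Callable[[int], object],
    seed: int = 0,
    standardize_features: bool = True,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with leakage-free standardization.

    ``model_factory(fold_seed)`` must return an unfitted object with
    ``fit`` / ``predict`` / ``predict_proba``. Standardization parameters
    are fitted on each fold's training split only. The headline metrics are
    the mean over folds; a pooled-confusion variant and the AUC of the
    pooled out-of-fold scores are also reported.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= k members (class sizes {counts.tolist()}, k={k})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31 - 1))
    fold_seeds = np.random.SeedSequence([int(seed), k]).generate_state(k) % (2**31 - 1)

    report = EvaluationReport(k=k, seed=int(seed))
    assignment = np.full(y.size, -1, dtype=int)
    oof_scores = np.zeros(y.size)
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        assignment[test_idx] = fold
        X_train, X_test = X[train_idx], X[test_idx]
        if standardize_features:
            params = fit_standardization(X_train)
            X_train = standardize(X_train, params)
            X_test = standardize(X_test, params)
        model = model_factory(int(fold_seeds[fold]))
        model.fit(X_train, y[train_idx])
        y_pred = np.asarray(model.predict(X_test), dtype=int)
        oof_scores[test_idx] = np.asarray(model.predict_proba(X_test))[:, 1]
        c = confusion_from_predictions(y[test_idx], y_pred)
        report.fold_confusions.append(c)
        report.fold_metrics.append(metrics(c))
    report.fold_assignment = assignment
    report.auc = roc_auc(oof_scores, y)
    return report
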