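"""Stratified k-fold cross-validation and per-behaviour evaluation metrics.

Per behaviour class the F1 score is the harmonic mean of recall
TP/(TP+FN) and precision TP/(TP+FP) under one-vs-rest collapsing of the
confusion matrix; the overall accuracy is the fraction of bouts whose
behaviour was correctly classified (trace over total, which equals the
one-vs-rest (TP+TN)/(TP+TN+FP+FN) form). Fold-level means come with 95%
confidence intervals using Student's t with k−1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io import ValidationError

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "CvReport",
    "stratified_folds",
    "f1_per_class",
    "overall_accuracy",
    "cross_validate",
]


@dataclass
class ConfusionMatrix:
    """Square count matrix indexed true x predicted over ``labels``."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValidationError("counts must be square over labels")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        labels: Sequence[str] | None = None,
    ) -> "ConfusionMatrix":
        if labels is None:
            labels = sorted(set(y_true) | set(y_pred))
        labels = tuple(labels)
        idx = {l: i for i, l in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(labels=labels, counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, label: str) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for one class against all others."""
        i = self.labels.index(label)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValidationError("cannot add confusion matrices over different labels")
        return ConfusionMatrix(self.labels, self.counts + other.counts)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest recall, precision and F1 for a single behaviour."""

    label: str
    recall: float
    precision: float
    f1: float


def f1_per_class(cm: ConfusionMatrix) -> list[ClassMetrics]:
    """Per-behaviour recall, precision and F1 = 2·R·P/(R+P).

    Degenerate denominators give 0: a class never predicted and never
    recovered scores F1 = 0, never NaN.
    """
    out = []
    for label in cm.labels:
        tp, _, fp, fn = cm.one_vs_rest(label)
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = (
            2 * recall * precision / (recall + precision)
            if recall + precision
            else 0.0
        )
        out.append(ClassMetrics(label, recall, precision, f1))
    return out


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of bouts correctly classified: trace(cm) / total."""
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def stratified_folds(
    y: Sequence[str], k: int = 10, seed: int = 0
) -> np.ndarray:
    """Assign each bout to one of ``k`` folds, preserving class proportions.

    Within every class the fold sizes differ by at most one; remainder
    bouts are dealt round-robin to folds in seeded-shuffled order, so
    the partition is 'semi-random' but proportionally representative.

    Raises if any class has fewer than ``k`` members — merge rare
    behaviour categories (e.g. galloping + trotting into running) before
    cross-validating.
    """
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    folds = np.full(len(y), -1, dtype=int)
    for label in sorted(set(y)):
        idx = np.flatnonzero(y == label)
        if len(idx) < k:
            raise ValidationError(
                f"class {label!r} has {len(idx)} members but {k} folds were "
                "requested; merge rare behaviour categories before CV"
            )
        rng.shuffle(idx)
        base, rem = divmod(len(idx), k)
        fold_order = rng.permutation(k)
        sizes = np.full(k, base, dtype=int)
        sizes[fold_order[:rem]] += 1
        pos = 0
        for f in range(k):
            folds[idx[pos : pos + sizes[f]]] = f
            pos += sizes[f]
    return folds


@dataclass
class CvReport:
    """Fold-level evaluation state of one stratified k-fold CV run."""

    method: str
    labels: tuple[str, ...]
    fold_cms: list[ConfusionMatrix]
    fold_accuracy: np.ndarray  # (k,)
    fold_f1: pd.DataFrame  # index = class label, columns = fold
    mean_accuracy: float = field(init=False)
    ci_accuracy: tuple[float, float] = field(init=False)
    mean_f1: pd.Series = field(init=False)
    ci_halfwidth_f1: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        k = len(self.fold_cms)
        self.fold_accuracy = np.asarray(self.fold_accuracy, dtype=float)
        hw = _t_halfwidth(self.fold_accuracy)
        self.mean_accuracy = float(self.fold_accuracy.mean())
        self.ci_accuracy = (self.mean_accuracy - hw, self.mean_accuracy + hw)
        self.mean_f1 = self.fold_f1.mean(axis=1)
        self.ci_halfwidth_f1 = self.fold_f1.apply(
            lambda row: _t_halfwidth(row.to_numpy()), axis=1
        )

    @property
    def pooled_cm(self) -> ConfusionMatrix:
        """Sum of fold confusion matrices = confusion of all out-of-fold predictions."""
        cm = self.fold_cms[0]
        for other in self.fold_cms[1:]:
            cm = cm + other
        return cm

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "labels": list(self.labels),
            "fold_accuracy": self.fold_accuracy.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "ci_accuracy": list(self.ci_accuracy),
            "mean_f1": self.mean_f1.to_dict(),
            "ci_halfwidth_f1": self.ci_halfwidth_f1.to_dict(),
            "fold_confusion": [cm.counts.tolist() for cm in self.fold_cms],
        }


def _t_halfwidth(x: np.ndarray, level: float = 0.95) -> float:
    """Half-width of the t-based CI of the mean over folds."""
    k = len(x)
    if k < 2 or np.allclose(x, x[0]):
        return 0.0
    tcrit = sstats.t.ppf(0.5 + level / 2, df=k - 1)
    return float(tcrit * x.std(ddof=1) / np.sqrt(k))


def cross_validate(
    method: str,
    X: pd.DataFrame,
    y: Sequence[str],
    hyperparams: dict | None = None,
    k: int = 10,
    seed: int = 0,
) -> CvReport:
    """Stratified k-fold CV: train on k−1 folds, score the held-out fold.

    The validation fold never enters training (no scaling leak: feature
    standardisation for SVM/ANN is fitted inside each training split).
    """
    from . import classify  # deferred: classify tunes via this module

    y = np.asarray(y, dtype=object)
    labels = tuple(sorted(set(y)))
    folds = stratified_folds(y, k=k, seed=seed)
    fold_cms = []
    fold_acc = []
    fold_f1 = {}
    for f in range(k):
        train = folds != f
        model = classify.train_classifier(
            method, X[train], y[train], hyperparams, seed=seed + f
        )
        pred = classify.predict(model, X[~train])
        cm = ConfusionMatrix.from_predictions(y[~train], pred, labels)
        fold_cms.append(cm)
        fold_acc.append(overall_accuracy(cm))
        fold_f1[f] = {m.label: m.f1 for m in f1_per_class(cm)}
    f1_df = pd.DataFrame(fold_f1).reindex(list(labels))
    return CvReport(
        method=method,
        labels=labels,
        fold_cms=fold_cms,
        fold_accuracy=np.array(fold_acc),
        fold_f1=f1_df,
    )
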