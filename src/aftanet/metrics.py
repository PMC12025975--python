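"""Evaluation metrics: balanced accuracy, AUROC, weighted F1, Cohen's kappa.

Implemented directly from their confusion-matrix definitions (the test
suite cross-checks each against scikit-learn).  AUROC uses the midrank
Mann-Whitney formulation, which equals the trapezoidal area under the ROC
curve and counts ties as one half.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion",
           "balanced_accuracy", "auroc", "weighted_f1", "cohens_kappa",
           "evaluate_predictions"]


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be non-negative")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(labels_true, labels_pred, n_classes: int) -> ConfusionMatrix:
    t = np.asarray(labels_true, dtype=np.int64)
    p = np.asarray(labels_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("label arrays must share a shape")
    if len(t) and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean per-class recall."""
    support = cm.counts.sum(axis=1)
    if np.any(support == 0):
        empty = np.flatnonzero(support == 0).tolist()
        raise ValueError(f"no true samples for classes {empty}")
    recalls = np.diag(cm.counts) / support
    return float(recalls.mean())


def auroc(scores, labels) -> float:
    """Area under the ROC curve for binary labels.

    Equals the probability that a random positive outranks a random
    negative, counting ties as one half (midrank handling).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not (pos.any() and neg.any()):
        raise ValueError("both classes must be present for AUROC")
    if pos.sum() + neg.sum() != len(labels):
        raise ValueError("labels must be binary 0/1")
    ranks = rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _precision_recall(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    tp = np.diag(cm.counts).astype(np.float64)
    pred_tot = cm.counts.sum(axis=0).astype(np.float64)
    true_tot = cm.counts.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(true_tot > 0, tp / true_tot, 0.0)
    return prec, rec


def weighted_f1(cm: ConfusionMatrix) -> float:
    """Support-weighted mean of per-class F1 scores.

    A class whose precision and recall are both zero contributes F1 = 0
    (reported with a warning)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    prec, rec = _precision_recall(cm)
    denom = prec + rec
    if np.any((denom == 0) & (cm.counts.sum(axis=1) > 0)):
        warnings.warn("class with zero precision+recall contributes F1=0")
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * prec * rec / denom, 0.0)
    support = cm.counts.sum(axis=1)
    return float((support * f1).sum() / cm.total)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1) / n
    col = cm.counts.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0:
        raise ValueError("degenerate table: expected agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class MetricsReport:
    """Scalar metrics plus per-class detail and the confusion matrix."""

    bac: float
    weighted_f1: float
    kappa: float
    auroc: float | None = None            # binary tasks only
    per_class_precision: list[float] = field(default_factory=list)
    per_class_recall: list[float] = field(default_factory=list)
    confusion: list[list[int]] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def summary_table(self) -> str:
        rows = [("BAC", self.bac),
                ("AUROC", self.auroc if self.auroc is not None else float("nan")),
                ("Weighted F1", self.weighted_f1),
                ("Kappa", self.kappa)]
        return "\n".join(f"{name:<12}{value:.4f}" for name, value in rows)


def evaluate_predictions(labels_true, labels_pred, n_classes: int,
                         scores=None) -> MetricsReport:
    """Bundle all metrics for one set of predictions.

    `scores` (positive-class probabilities) enables AUROC for binary tasks.
    """
    cm = confusion(labels_true, labels_pred, n_classes)
    prec, rec = _precision_recall(cm)
    roc = None
    if scores is not None and n_classes == 2:
        roc = auroc(scores, labels_true)
    return MetricsReport(
        bac=balanced_accuracy(cm), weighted_f1=weighted_f1(cm),
        kappa=cohens_kappa(cm), auroc=roc,
        per_class_precision=[float(x) for x in prec],
        per_class_recall=[float(x) for x in rec],
        confusion=cm.counts.tolist())
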