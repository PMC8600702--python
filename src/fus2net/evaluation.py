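"""Binary-classification evaluation: confusion counts, the four ratio
metrics (accuracy, sensitivity, specificity, precision), and ROC/AUC.

Malignant is the positive class throughout: sensitivity is the probability
a malignant tumor is called malignant (low missed-diagnosis rate),
specificity the probability a benign tumor is called benign (low
misdiagnosis rate). Ratios with a zero denominator are reported as NaN and
flagged, never silently zero-filled, so degenerate folds stay visible.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .data import LabeledDataset
from .preprocess import as_batch


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ROCCurve:
    """Threshold-sweep operating points, from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def trapezoid_area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))

    def save_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fpr", "tpr", "threshold"])
            for f, t, th in zip(self.fpr, self.tpr, self.thresholds):
                w.writerow([f, t, th])


@dataclass
class EvalResult:
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float = math.nan
    roc: ROCCurve | None = None
    #: names of metrics whose denominator was zero (value reported as NaN)
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "counts": {
                "TP": self.counts.tp,
                "TN": self.counts.tn,
                "FP": self.counts.fp,
                "FN": self.counts.fn,
            },
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "auc": self.auc,
            "undefined": self.undefined,
        }

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with malignant (label 1) as positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def metrics(counts: ConfusionCounts) -> EvalResult:
    """Accuracy, sensitivity, specificity and precision from raw counts.

    accuracy = (TP+TN)/(TP+FP+FN+TN); sensitivity = TP/(TP+FN);
    specificity = TN/(FP+TN); precision = TP/(TP+FP).
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics for zero samples")
    undef: list[str] = []
    return EvalResult(
        counts=counts,
        accuracy=(counts.tp + counts.tn) / counts.total,
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn, "sensitivity", undef),
        specificity=_ratio(counts.tn, counts.fp + counts.tn, "specificity", undef),
        precision=_ratio(counts.tp, counts.tp + counts.fp, "precision", undef),
        undefined=undef,
    )


def roc_auc(y_true, y_scores) -> tuple[ROCCurve, float]:
    """ROC curve (threshold sweep) and AUC.

    The AUC equals the probability that a random positive outscores a random
    negative, ties counting one half (the rank-statistic convention).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_scores = np.asarray(y_scores, dtype=float)
    if len(set(y_true.tolist())) < 2:
        raise ValueError("roc_auc needs both classes present")
    fpr, tpr, thr = roc_curve(y_true, y_scores)
    auc = float(roc_auc_score(y_true, y_scores))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr), auc


def evaluate_scores(y_true, y_scores, threshold: float = 0.5) -> EvalResult:
    """Full evaluation from malignant-class scores: hard labels at 0.5."""
    y_true = np.asarray(y_true, dtype=int)
    y_scores = np.asarray(y_scores, dtype=float)
    y_pred = (y_scores >= threshold).astype(int)
    result = metrics(confusion(y_true, y_pred))
    if len(set(y_true.tolist())) == 2:
        result.roc, result.auc = roc_auc(y_true, y_scores)
    else:
        result.undefined.append("auc")
    return result


def evaluate_model(model, dataset: LabeledDataset) -> EvalResult:
    """Evaluate a built model on a preprocessed dataset.

    The dataset must already be resized/channel-converted exactly as in
    training (no augmentation); standardization is applied here as the last
    step before the network. Predicted label is the argmax class; the score
    is the malignant-class probability.
    """
    from .arch import forward

    if len(dataset) == 0:
        raise ValueError("empty evaluation dataset")
    probs = []
    batch_size = 16
    for i in range(0, len(dataset), batch_size):
        chunk = dataset.samples[i : i + batch_size]
        probs.append(forward(model, as_batch(chunk)))
    p = np.concatenate(probs)
    return evaluate_scores(dataset.labels_int(), p[:, 1])
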