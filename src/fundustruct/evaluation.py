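"""Classifier evaluation: per-class sensitivity / precision / F1 and ROC/AUC.

Glaucoma is the positive class for the ROC.  Metrics with a zero
denominator are reported as NaN with a warning rather than silently
coerced to 0, so degenerate classifiers remain visible in ablation
comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics

from .classifier import CLASSES, GlaucomaModel, evaluate_accuracy


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    per_class: dict                      # class -> {sensitivity, precision, f1}
    roc_points: list = field(default_factory=list)   # [(fpr, tpr), ...]
    auc: float = float("nan")
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "per_class": self.per_class,
            "auc": self.auc,
            "roc": [[float(f), float(t)] for f, t in self.roc_points],
            **self.extra,
        }
        return json.dumps(payload, indent=2, allow_nan=True)


def confusion_from_predictions(labels: list[str], predictions: list[str],
                               positive: str) -> ConfusionCounts:
    if len(labels) != len(predictions):
        raise ValueError(f"length mismatch: {len(labels)} labels vs {len(predictions)} predictions")
    if not labels:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    tp = sum(1 for l, p in zip(labels, predictions) if l == positive and p == positive)
    fn = sum(1 for l, p in zip(labels, predictions) if l == positive and p != positive)
    fp = sum(1 for l, p in zip(labels, predictions) if l != positive and p == positive)
    tn = sum(1 for l, p in zip(labels, predictions) if l != positive and p != positive)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, precision, f1); undefined ratios come back as NaN."""
    sens = _safe_ratio(c.tp, c.tp + c.fn, "sensitivity")
    prec = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    if np.isnan(sens) or np.isnan(prec) or (sens + prec) == 0:
        if not (np.isnan(sens) or np.isnan(prec)):
            warnings.warn("f1 undefined (sensitivity + precision is zero); reported as NaN",
                          stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return sens, prec, f1


def roc_curve(labels: list[str], scores: list[float],
              positive: str = "glaucoma") -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC for positive-class probabilities."""
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must be probabilities in [0, 1]")
    y = np.array([1 if l == positive else 0 for l in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(y, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def report_from_predictions(labels: list[str], predictions: list[str],
                            scores: list[float] | None = None) -> EvalReport:
    per_class = {}
    for cls in CLASSES:
        sens, prec, f1 = metrics(confusion_from_predictions(labels, predictions, cls))
        per_class[cls] = {"sensitivity": sens, "precision": prec, "f1": f1}
    report = EvalReport(per_class=per_class)
    if scores is not None and len(set(labels)) > 1:
        report.roc_points, report.auc = roc_curve(labels, scores)
    return report


def evaluate_model(model: GlaucomaModel, samples: list[tuple[tuple, str]]) -> EvalReport:
    """Full report on labeled (image, vessel, disc) triples; glaucoma is
    the ROC-positive class."""
    labels = [lab for _, lab in samples]
    acc, probs = evaluate_accuracy(model, samples)
    predictions = [CLASSES[i] for i in probs.argmax(axis=1)]
    scores = probs[:, CLASSES.index("glaucoma")].tolist()
    report = report_from_predictions(labels, predictions,
                                     scores if len(set(labels)) > 1 else None)
    report.extra["accuracy"] = acc
    report.extra["n_samples"] = len(samples)
    report.extra["fusion"] = model.fusion.mode
    return report
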