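"""Confusion-matrix metrics, ROC curve and AUC.

Both tasks are scored with accuracy, specificity and sensitivity.  For
binary classification these are the usual TN- and TP-recalls; for the
3-tag segmentation task, sensitivity is the macro-average of per-tag
recall and specificity the macro-average of per-tag one-vs-rest
specificity (the only standard extension that yields one number per
metric).  The ROC curve is a threshold sweep over the unique scores and
AUC the trapezoidal area, which equals the rank (Mann-Whitney U)
statistic with tie rank-averaging.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .corpus import TAGS

__all__ = ["EvalReport", "classification_metrics", "segmentation_metrics", "roc_auc"]


@dataclass
class EvalReport:
    task: str
    accuracy: float
    specificity: float
    sensitivity: float
    confusion: np.ndarray
    n: int
    roc_points: list[tuple[float, float]] | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "confusion": self.confusion.tolist(),
            "n": self.n,
            "roc_points": self.roc_points,
            "auc": self.auc,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        lines = [
            f"task: {self.task} (n={self.n})",
            f"  accuracy    {self.accuracy:.4f}",
            f"  specificity {self.specificity:.4f}",
            f"  sensitivity {self.sensitivity:.4f}",
        ]
        if self.auc is not None:
            lines.append(f"  auc         {self.auc:.4f}")
        return "\n".join(lines)

    def write_roc_csv(self, path) -> None:
        if self.roc_points is None:
            raise ValueError("report has no ROC points")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("fpr,tpr\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr},{tpr}\n")


def classification_metrics(
    labels, predictions, positive_class: int = 1
) -> EvalReport:
    """Binary accuracy/specificity/sensitivity; positive class defaults to 1
    (Yin deficiency)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must align")
    n = labels.size
    pos = labels == positive_class
    tp = int(np.sum(pos & (predictions == positive_class)))
    fn = int(np.sum(pos & (predictions != positive_class)))
    tn = int(np.sum(~pos & (predictions != positive_class)))
    fp = int(np.sum(~pos & (predictions == positive_class)))
    accuracy = (tp + tn) / n
    if tp + fn == 0:
        warnings.warn("no positive examples; sensitivity undefined")
        sensitivity = math.nan
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative examples; specificity undefined")
        specificity = math.nan
    else:
        specificity = tn / (tn + fp)
    confusion = np.array([[tn, fp], [fn, tp]])
    return EvalReport(
        task="classification",
        accuracy=accuracy,
        specificity=specificity,
        sensitivity=sensitivity,
        confusion=confusion,
        n=n,
    )


def segmentation_metrics(gold_tags, predicted_tags, masks=None) -> EvalReport:
    """Character-tag metrics over masked-in positions.

    Accepts flat index sequences or per-sentence (batch, len) arrays plus
    masks.  Accuracy is micro (fraction of characters correctly tagged);
    sensitivity/specificity are macro over the three tags.
    """
    gold = np.asarray(gold_tags)
    pred = np.asarray(predicted_tags)
    if gold.shape != pred.shape:
        raise ValueError("gold and predicted tags must align")
    if masks is not None:
        masks = np.asarray(masks, dtype=bool)
        gold = gold[masks]
        pred = pred[masks]
    gold = gold.ravel()
    pred = pred.ravel()
    n = gold.size
    k = len(TAGS)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (gold, pred), 1)
    accuracy = np.trace(confusion) / n
    recalls, specs = [], []
    for t in range(k):
        support = confusion[t].sum()
        if support > 0:
            recalls.append(confusion[t, t] / support)
        negatives = n - support
        if negatives > 0:
            fp = confusion[:, t].sum() - confusion[t, t]
            specs.append((negatives - fp) / negatives)
    return EvalReport(
        task="segmentation",
        accuracy=float(accuracy),
        specificity=float(np.mean(specs)) if specs else math.nan,
        sensitivity=float(np.mean(recalls)) if recalls else math.nan,
        confusion=confusion,
        n=int(n),
    )


def roc_auc(labels, scores, positive_class: int = 1) -> tuple[list[tuple[float, float]], float]:
    """ROC points ((0,0) to (1,1)) and trapezoidal AUC.

    Thresholds sweep the unique scores from high to low; tied scores move
    as a block, which makes the trapezoidal area equal the rank-based
    (tie-rank-averaged) U-statistic estimator.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep only the last index of each tied-score block
    last = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc
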