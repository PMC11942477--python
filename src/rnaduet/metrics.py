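"""Evaluation metrics for structure and classification tasks.

Pair-level structure scoring counts each base pair once (strict upper
triangle, exact matching, no positional slack). PPV/Sen/F1, MCC and ACC
follow the standard confusion-count formulas with the zero-denominator
convention of 0. Threshold-free metrics (AUROC with mid-rank tie
handling, AUPRC by precision-recall step integration) delegate to
scikit-learn.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .structure import PairMatrix


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN and (optionally) TN aggregates.

    TN is None for pair-level structure scoring, where the enormous
    negative class is implicit and TN-based metrics are undefined.
    """

    tp: int
    fp: int
    fn: int
    tn: Optional[int] = None

    def __post_init__(self):
        for v in (self.tp, self.fp, self.fn):
            if v < 0:
                raise ValueError("counts must be nonnegative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("counts must be nonnegative")


def pair_confusion(pred: PairMatrix, truth: PairMatrix,
                   with_tn: bool = False) -> ConfusionCounts:
    """Confusion counts over the strict upper triangle of two pair matrices."""
    if pred.L != truth.L:
        raise ValueError(f"length mismatch: {pred.L} vs {truth.L}")
    tp = len(pred.pairs & truth.pairs)
    fp = len(pred.pairs - truth.pairs)
    fn = len(truth.pairs - pred.pairs)
    tn = None
    if with_tn:
        total = pred.L * (pred.L - 1) // 2
        tn = total - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def binary_confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Element-wise confusion counts for two binary arrays of equal shape."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def ppv_sen_f1(c: ConfusionCounts) -> Tuple[float, float, float]:
    """Positive predictive value, sensitivity and their harmonic mean F1."""
    ppv = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    sen = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    f1 = 2 * ppv * sen / (ppv + sen) if ppv + sen else 0.0
    return ppv, sen, f1


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    if c.tn is None:
        raise ValueError("MCC requires TN")
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def acc(c: ConfusionCounts) -> float:
    """Fraction of correctly classified samples."""
    if c.tn is None:
        raise ValueError("ACC requires TN")
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise ValueError("empty counts")
    return (c.tp + c.tn) / total


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic, mid-rank tie handling)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step integration)."""
    return float(average_precision_score(np.asarray(labels),
                                         np.asarray(scores, dtype=np.float64)))


def metric_report(c: ConfusionCounts, scores=None, labels=None) -> Dict[str, float]:
    """Assemble the standard report dictionary (names are stable)."""
    ppv, sen, f1 = ppv_sen_f1(c)
    report = {"PPV": ppv, "SEN": sen, "F1": f1}
    if c.tn is not None:
        report["MCC"] = mcc(c)
        report["ACC"] = acc(c)
    if scores is not None and labels is not None:
        report["AUROC"] = auroc(scores, labels)
        report["AUPRC"] = auprc(scores, labels)
    return report


def write_report(report: Dict[str, float], path) -> None:
    """Write a report both as TSV (.tsv) and JSON (.json) side by side."""
    path = str(path)
    stem = path.rsplit(".", 1)[0] if "." in path else path
    with open(stem + ".json", "w") as f:
        json.dump(report, f, indent=2)
        f.write("\n")
    with open(stem + ".tsv", "w") as f:
        for k, v in report.items():
            f.write(f"{k}\t{v:.6f}\n")
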