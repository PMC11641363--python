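"""Classification metrics and the paired McNemar comparison.

Accuracy, sensitivity, specificity and the Matthews correlation
coefficient are computed exactly from confusion counts:

    ACC = (TP+TN) / (TP+TN+FP+FN)
    SN  = TP / (TP+FN)
    SP  = TN / (TN+FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is defined as 0 when any denominator factor vanishes.  AUC is the
rank-based (Mann-Whitney) area under the ROC curve.  Model pairs are
compared with the exact-binomial McNemar test on discordant predictions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None

    def as_row(self) -> str:
        """TSV row in the conventional SN / SP / ACC / MCC / AUC order."""
        auc = f"{self.auc:.4f}" if self.auc is not None else "-"
        return (f"{self.sn:.4f}\t{self.sp:.4f}\t{self.acc:.4f}\t"
                f"{self.mcc:.4f}\t{auc}")


def confusion(predicted_probs, labels,
              threshold: float = 0.5) -> ConfusionCounts:
    """Threshold probabilities at ``threshold`` and tally the confusion."""
    probs = np.asarray(predicted_probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.shape != labels.shape:
        raise ValueError("predictions and labels must align")
    pred = (probs >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (labels == 1))),
        tn=int(np.sum((pred == 0) & (labels == 0))),
        fp=int(np.sum((pred == 1) & (labels == 0))),
        fn=int(np.sum((pred == 0) & (labels == 1))),
    )


def metrics(counts: ConfusionCounts) -> MetricReport:
    """ACC/SN/SP/MCC from confusion counts (MCC=0 on a zero denominator)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total == 0:
        raise ValueError("no samples")
    acc = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricReport(acc=acc, sn=sn, sp=sp, mcc=mcc)


def counts_from_rates(sn: float, sp: float, n_pos: int,
                      n_neg: int) -> ConfusionCounts:
    """Invert SN/SP on known class sizes back to confusion counts."""
    tp = round(sn * n_pos)
    tn = round(sp * n_neg)
    return ConfusionCounts(tp=tp, tn=tn, fp=n_neg - tn, fn=n_pos - tp)


def auc(predicted_probs, labels) -> float:
    """Rank-based AUC; ties get midranks. Requires both classes present."""
    probs = np.asarray(predicted_probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, probs))


def evaluate(predicted_probs, labels, threshold: float = 0.5) -> MetricReport:
    """Full report (ACC/SN/SP/MCC/AUC) from probabilities and labels."""
    counts = confusion(predicted_probs, labels, threshold)
    report = metrics(counts)
    labels_arr = np.asarray(labels).astype(int)
    auc_value = auc(predicted_probs, labels) \
        if len(np.unique(labels_arr)) == 2 else None
    return MetricReport(acc=report.acc, sn=report.sn, sp=report.sp,
                        mcc=report.mcc, auc=auc_value)


def mcnemar(preds_a, preds_b, labels) -> float:
    """Exact-binomial McNemar p-value on two classifiers' predictions.

    Discordant pairs are samples one classifier gets right and the other
    wrong; under the null they split Binomial(n, 1/2).
    """
    preds_a = np.asarray(preds_a).astype(int)
    preds_b = np.asarray(preds_b).astype(int)
    labels = np.asarray(labels).astype(int)
    if not (preds_a.shape == preds_b.shape == labels.shape):
        raise ValueError("prediction vectors and labels must align")
    a_ok = preds_a == labels
    b_ok = preds_b == labels
    b01 = int(np.sum(a_ok & ~b_ok))
    b10 = int(np.sum(~a_ok & b_ok))
    if b01 + b10 == 0:
        warnings.warn("no discordant pairs; McNemar p-value is 1",
                      stacklevel=2)
        return 1.0
    return float(binomtest(b01, b01 + b10, 0.5).pvalue)
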