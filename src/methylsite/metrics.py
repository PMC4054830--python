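"""Prediction-quality metrics and the balanced-subset jackknife protocol.

Sensitivity, specificity, accuracy and the Matthews correlation coefficient
are computed in the intuitive class-total form: with N+ positives of which
N-+ are missed, and N- negatives of which N+- are miscalled,

    Sn  = 1 - N-+/N+
    Sp  = 1 - N+-/N-
    Acc = 1 - (N-+ + N+-)/(N+ + N-)
    MCC = (1 - (N-+/N+ + N+-/N-)) /
          sqrt((1 + (N+- - N-+)/N+) (1 + (N-+ - N+-)/N-))

This parameterization is algebraically identical to the textbook TP/TN/FP/FN
formulas (N+ = TP+FN, N- = TN+FP, N-+ = FN, N+- = FP).  When the MCC
denominator vanishes (a single-class prediction), MCC is reported as 0 by
convention; an empty class makes Sn or Sp undefined and is reported as None
rather than silently zero.

Evaluation follows the leave-one-out (jackknife) protocol: each sample is
predicted by a model trained on all remaining samples, and metrics are
computed from the pooled counts.  The imbalanced benchmark is handled by
pairing the positives with each of the seven near-equal negative subsets in
turn and averaging the per-subset metrics arithmetically.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import predict_labels, train_svm


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")


@dataclass(frozen=True)
class ChouCounts:
    """Class totals and miss counts: (N+, N-, N-+, N+-)."""

    n_pos: int
    n_neg: int
    miss_pos: int  # positives predicted negative (N-+)
    miss_neg: int  # negatives predicted positive (N+-)

    def __post_init__(self) -> None:
        if not 0 <= self.miss_pos <= self.n_pos:
            raise MetricsError("miss_pos must satisfy 0 <= N-+ <= N+")
        if not 0 <= self.miss_neg <= self.n_neg:
            raise MetricsError("miss_neg must satisfy 0 <= N+- <= N-")


@dataclass(frozen=True)
class MetricSet:
    """Sn/Sp/Acc in [0, 1] and MCC in [-1, 1]; None marks undefined."""

    sn: Optional[float]
    sp: Optional[float]
    acc: Optional[float]
    mcc: Optional[float]


def confusion_to_chou(c: ConfusionCounts) -> ChouCounts:
    return ChouCounts(
        n_pos=c.tp + c.fn, n_neg=c.tn + c.fp, miss_pos=c.fn, miss_neg=c.fp
    )


def chou_to_confusion(c: ChouCounts) -> ConfusionCounts:
    return ConfusionCounts(
        tp=c.n_pos - c.miss_pos,
        tn=c.n_neg - c.miss_neg,
        fp=c.miss_neg,
        fn=c.miss_pos,
    )


def chou_metrics(c: ChouCounts) -> MetricSet:
    """Compute Sn/Sp/Acc/MCC from class-total counts."""
    sn = None if c.n_pos == 0 else 1.0 - c.miss_pos / c.n_pos
    sp = None if c.n_neg == 0 else 1.0 - c.miss_neg / c.n_neg
    total = c.n_pos + c.n_neg
    acc = None if total == 0 else 1.0 - (c.miss_pos + c.miss_neg) / total
    if c.n_pos == 0 or c.n_neg == 0:
        mcc = 0.0
    else:
        numerator = 1.0 - (c.miss_pos / c.n_pos + c.miss_neg / c.n_neg)
        f1 = 1.0 + (c.miss_neg - c.miss_pos) / c.n_pos
        f2 = 1.0 + (c.miss_pos - c.miss_neg) / c.n_neg
        denom_sq = f1 * f2
        mcc = 0.0 if denom_sq <= 0.0 else numerator / math.sqrt(denom_sq)
        mcc = min(1.0, max(-1.0, mcc))  # guard float overshoot at the limits
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    return chou_metrics(confusion_to_chou(c))


def counts_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ChouCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise MetricsError("prediction and truth vectors differ in length")
    pos = y_true == 1
    neg = y_true == -1
    return ChouCounts(
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
        miss_pos=int(np.sum(pos & (y_pred == -1))),
        miss_neg=int(np.sum(neg & (y_pred == 1))),
    )


def loo_predictions(
    X: np.ndarray, y: np.ndarray, c: float, gamma: float
) -> np.ndarray:
    """Leave-one-out predicted labels: sample i is predicted by a model
    trained on all other samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < 2:
        raise MetricsError("jackknife needs at least 2 samples")
    pred = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        m = train_svm(X[mask], y[mask], c, gamma)
        pred[i] = predict_labels(m, X[i : i + 1])[0][0]
        mask[i] = True
    return pred


def jackknife_evaluate(
    X: np.ndarray, y: np.ndarray, c: float, gamma: float
) -> MetricSet:
    """Leave-one-out evaluation; metrics from the pooled counts."""
    return chou_metrics(counts_from_predictions(y, loo_predictions(X, y, c, gamma)))


def average_reports(reports: Sequence[MetricSet]) -> MetricSet:
    """Component-wise arithmetic mean; None in any input propagates."""
    if not reports:
        raise MetricsError("cannot average an empty list of reports")

    def mean_of(values):
        if any(v is None for v in values):
            return None
        return float(np.mean(values))

    return MetricSet(
        sn=mean_of([r.sn for r in reports]),
        sp=mean_of([r.sp for r in reports]),
        acc=mean_of([r.acc for r in reports]),
        mcc=mean_of([r.mcc for r in reports]),
    )


@dataclass
class JackknifeReport:
    """Per-subset and averaged metrics over the balanced jackknife runs."""

    per_subset: list[MetricSet]
    averaged: MetricSet
    subset_sizes: list[int]
    config_fingerprint: str


def run_balanced_jackknife(
    X_pos: np.ndarray,
    neg_subsets: Sequence[np.ndarray],
    c: float,
    gamma: float,
) -> JackknifeReport:
    """Evaluate positives against each negative subset independently.

    Each run pools the full positive set with one negative subset, performs
    leave-one-out evaluation with a model retrained per held-out sample, and
    the per-subset metric sets are averaged arithmetically.
    """
    X_pos = np.asarray(X_pos, dtype=float)
    per_subset = []
    sizes = []
    for X_neg in neg_subsets:
        X_neg = np.asarray(X_neg, dtype=float)
        X = np.vstack([X_pos, X_neg])
        y = np.concatenate(
            [np.ones(len(X_pos), dtype=int), -np.ones(len(X_neg), dtype=int)]
        )
        per_subset.append(jackknife_evaluate(X, y, c, gamma))
        sizes.append(len(X_neg))
    fingerprint = hashlib.sha256(
        f"{len(X_pos)}|{sizes}|{c}|{gamma}".encode()
    ).hexdigest()[:16]
    return JackknifeReport(
        per_subset=per_subset,
        averaged=average_reports(per_subset),
        subset_sizes=sizes,
        config_fingerprint=fingerprint,
    )


def write_report_tsv(report: JackknifeReport, path: str | Path) -> None:
    """Write per-subset rows plus an Average row (Acc%/MCC/Sn%/Sp%)."""

    def fmt(v, percent):
        if v is None:
            return "NA"
        return f"{100 * v:.2f}" if percent else f"{v:.2f}"

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["negative_subset", "acc_pct", "mcc", "sn_pct", "sp_pct"])
        for i, m in enumerate(report.per_subset, start=1):
            writer.writerow(
                [i, fmt(m.acc, True), fmt(m.mcc, False), fmt(m.sn, True), fmt(m.sp, True)]
            )
        a = report.averaged
        writer.writerow(
            ["Average", fmt(a.acc, True), fmt(a.mcc, False), fmt(a.sn, True), fmt(a.sp, True)]
        )
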