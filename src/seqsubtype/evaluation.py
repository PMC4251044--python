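"""Confusion-count bookkeeping, threshold metrics and ROC curves.

Per-class metrics follow the usual one-vs-rest definitions on percent
scale:

* sensitivity  SEN = TP / (TP + FN) * 100
* specificity  SPE = TN / (TN + FP) * 100
* accuracy     ACC = (TP + TN) / (TP + TN + FP + FN) * 100
* error rate   ERR = (FP + FN) / (TP + TN + FP + FN) * 100
* precision    PER = TP / (TP + FP) * 100
* MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator is zero is reported as 0 and flagged, so a
class with no positive predictions yields PER = MCC = 0 rather than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricRow:
    """Per-class metric values (percent scale except MCC)."""

    acc: float
    err: float
    mcc: float
    precision: float
    sensitivity: float
    specificity: float
    zero_denominator: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc, "err": self.err, "mcc": self.mcc,
            "precision": self.precision, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass(frozen=True)
class RocCurve:
    """One-vs-rest ROC curve with trapezoid AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def metrics_from_counts(c: ConfusionCounts) -> MetricRow:
    """Derive the six per-class metrics from one-vs-rest counts."""
    flags: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den * 100.0

    total = c.total
    acc = ratio(c.tp + c.tn, total, "acc")
    err = ratio(c.fp + c.fn, total, "err")
    sen = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spe = ratio(c.tn, c.tn + c.fp, "specificity")
    per = ratio(c.tp, c.tp + c.fp, "precision")
    mcc_den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if mcc_den == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / mcc_den
    return MetricRow(
        acc=acc, err=err, mcc=mcc, precision=per,
        sensitivity=sen, specificity=spe, zero_denominator=tuple(flags),
    )


def confusion_matrix(true_labels, predicted_labels, classes=None):
    """k x k confusion matrix plus per-class one-vs-rest counts.

    Entry (i, j) counts records of true class i predicted as class j.
    Returns ``(matrix, counts)`` where ``matrix`` is a labelled DataFrame
    and ``counts`` maps class -> :class:`ConfusionCounts`.
    """
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label lists must have equal length")
    if classes is None:
        classes = sorted(set(t) | set(p), key=str)
    else:
        classes = list(classes)
        extra = (set(t) | set(p)) - set(classes)
        if extra:
            raise ValueError(f"labels outside the class set: {sorted(extra, key=str)}")
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    mat = np.zeros((k, k), dtype=int)
    for a, b in zip(t, p):
        mat[index[a], index[b]] += 1
    total = mat.sum()
    counts = {}
    for c in classes:
        i = index[c]
        tp = int(mat[i, i])
        fn = int(mat[i].sum() - tp)
        fp = int(mat[:, i].sum() - tp)
        tn = int(total - tp - fn - fp)
        counts[c] = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    return pd.DataFrame(mat, index=classes, columns=classes), counts


def roc_curve(scores, positives) -> RocCurve:
    """One-vs-rest ROC from per-record scores and the positive indicator.

    ``positives`` is a boolean mask (or 0/1 labels) aligned with
    ``scores``.  The curve sweeps the unique score thresholds; the AUC is
    the trapezoid area, which equals the Mann-Whitney probability that a
    random positive outscores a random negative (ties counted half).
    """
    y = np.asarray(positives).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("roc_curve needs at least one positive and one negative")
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


def write_roc_table(roc: RocCurve, path) -> None:
    """Write ROC points (threshold, fpr, tpr) plus the AUC as a TSV."""
    df = pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr})
    df["auc"] = roc.auc
    df.to_csv(path, sep="\t", index=False)


def macro_average(rows: list[MetricRow]) -> MetricRow:
    """Unweighted mean of per-class metric rows."""
    if not rows:
        raise ValueError("macro_average requires at least one row")
    flags = tuple(sorted({f for r in rows for f in r.zero_denominator}))
    return MetricRow(
        acc=float(np.mean([r.acc for r in rows])),
        err=float(np.mean([r.err for r in rows])),
        mcc=float(np.mean([r.mcc for r in rows])),
        precision=float(np.mean([r.precision for r in rows])),
        sensitivity=float(np.mean([r.sensitivity for r in rows])),
        specificity=float(np.mean([r.specificity for r in rows])),
        zero_denominator=flags,
    )


def metric_report(true_labels, predicted_labels, classes=None) -> dict:
    """Full per-class + macro report as a JSON-ready dictionary.

    Percent metrics are rounded to 2 decimals and MCC to 5, the precision
    conventional for published classifier tables.
    """
    mat, counts = confusion_matrix(true_labels, predicted_labels, classes)
    per_class = {}
    rows = []
    for c in mat.index:
        row = metrics_from_counts(counts[c])
        rows.append(row)
        cc = counts[c]
        per_class[str(c)] = {
            "acc": round(row.acc, 2), "err": round(row.err, 2),
            "mcc": round(row.mcc, 5), "precision": round(row.precision, 2),
            "sensitivity": round(row.sensitivity, 2),
            "specificity": round(row.specificity, 2),
            "tp": cc.tp, "fp": cc.fp, "tn": cc.tn, "fn": cc.fn,
        }
    overall = macro_average(rows)
    n = int(mat.to_numpy().sum())
    return {
        "n": n,
        "overall_accuracy": round(float(np.trace(mat.to_numpy()) / n * 100.0), 2),
        "per_class": per_class,
        "macro": {
            "acc": round(overall.acc, 2), "err": round(overall.err, 2),
            "mcc": round(overall.mcc, 5), "precision": round(overall.precision, 2),
            "sensitivity": round(overall.sensitivity, 2),
            "specificity": round(overall.specificity, 2),
        },
        "confusion_matrix": {str(c): [int(v) for v in mat.loc[c]] for c in mat.index},
        "class_order": [str(c) for c in mat.index],
    }
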