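"""Classification metrics computed from a confusion matrix.

All metrics take a confusion matrix C where C[i, j] counts samples of true
class i predicted as class j. Balanced accuracy is the unweighted mean of
per-class recall; F1 is the per-class harmonic mean of precision and
recall, aggregated by support-weighted (default) or macro averaging; MCC
uses the standard multiclass (Gorodkin) generalization, which reduces to
the familiar binary formula

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

for 2x2 inputs. Zero denominators yield 0 with a warning; an all-zero
confusion matrix raises :class:`UndefinedMetricError`.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import UndefinedMetricError


def _validate(confusion) -> np.ndarray:
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {c.shape}")
    if (c < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    if c.sum() == 0:
        raise UndefinedMetricError("all-zero confusion matrix")
    return c


def confusion_matrix(y_true, y_pred, labels) -> np.ndarray:
    """Count matrix with rows = true labels, columns = predictions."""
    index = {lab: i for i, lab in enumerate(labels)}
    c = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        c[index[t], index[p]] += 1
    return c


def per_class_recall(confusion) -> np.ndarray:
    c = _validate(confusion)
    support = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.diag(c) / support
    if np.isnan(recall).any():
        warnings.warn("class with zero support; its recall set to 0")
        recall = np.nan_to_num(recall)
    return recall


def balanced_accuracy(confusion) -> float:
    """Unweighted mean of per-class recall."""
    return float(per_class_recall(confusion).mean())


def binary_precision_balanced_accuracy(confusion) -> float:
    """The precision-based binary variant (TP/(TP+FP) + TN/(TN+FN)) / 2.

    Provided for completeness next to the conventional mean-recall
    definition; only defined for 2x2 confusion matrices with the positive
    class in row/column 0.
    """
    c = _validate(confusion)
    if c.shape != (2, 2):
        raise ValueError("the precision-based variant is binary only")
    tp, fn, fp, tn = c[0, 0], c[0, 1], c[1, 0], c[1, 1]
    terms = []
    for num, den in ((tp, tp + fp), (tn, tn + fn)):
        if den == 0:
            warnings.warn("zero denominator; term set to 0")
            terms.append(0.0)
        else:
            terms.append(num / den)
    return float((terms[0] + terms[1]) / 2)


def per_class_f1(confusion) -> np.ndarray:
    """F1 = 2PR/(P+R) for each class (equivalently 2TP/(2TP+FP+FN))."""
    c = _validate(confusion)
    support = c.sum(axis=1)
    predicted = c.sum(axis=0)
    diag = np.diag(c)
    denom = support + predicted
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * diag / denom, 0.0)
    return f1


def f1_score(confusion, average: str = "weighted") -> float:
    """Per-class F1 = 2PR/(P+R), aggregated across classes.

    average: "weighted" (support-weighted mean, default) or "macro".
    """
    c = _validate(confusion)
    support = c.sum(axis=1)
    predicted = c.sum(axis=0)
    diag = np.diag(c)
    f1 = np.zeros(len(diag))
    for k in range(len(diag)):
        denom = support[k] + predicted[k]  # == (P+R) scaled; 2TP/(2TP+FP+FN)
        if denom == 0:
            warnings.warn(f"class {k} absent from truth and predictions; F1 set to 0")
            continue
        f1[k] = 2.0 * diag[k] / denom
    if average == "macro":
        return float(f1.mean())
    if average == "weighted":
        total = support.sum()
        if total == 0:
            raise UndefinedMetricError("no support in confusion matrix")
        return float((f1 * support).sum() / total)
    raise ValueError(f"unknown average: {average!r}")


def mcc(confusion) -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin form)."""
    c = _validate(confusion)
    t = c.sum(axis=1)  # true counts per class
    p = c.sum(axis=0)  # predicted counts per class
    s = c.sum()
    cov = np.trace(c) * s - float(t @ p)
    denom = np.sqrt(s**2 - float(p @ p)) * np.sqrt(s**2 - float(t @ t))
    if denom == 0:
        warnings.warn("degenerate confusion matrix; MCC set to 0")
        return 0.0
    return float(cov / denom)
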