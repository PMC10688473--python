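"""Evaluation metrics implemented from their defining formulas.

Precision, recall and F1 are set-based over (sample, label) pairs:
precision = |y ∩ y'| / |y|, recall = |y ∩ y'| / |y'| with y the predicted
and y' the true pair sets.  Macro-F1 is the unweighted mean of per-class
F1 (a support-weighted variant is available).  The multiclass Matthews
correlation coefficient is the Gorodkin generalization over a K x K
confusion matrix.  Average precision sums precision at each distinct
descending score threshold weighted by the recall increment, with tied
scores grouped.  One-vs-rest relabeling and a score-orientation transform
(1 - s for tools whose convention is inverted) support cross-method
comparison.

Zero-denominator conventions: precision/recall/F1 and MCC return 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "precision_recall_f1",
    "per_class_prf",
    "macro_f1",
    "confusion_matrix",
    "mcc_multiclass",
    "one_vs_rest",
    "average_precision",
    "orient_scores",
    "evaluation_report",
]


def precision_recall_f1(y_pred_set: set, y_true_set: set) -> tuple[float, float, float]:
    """Set-based precision, recall, F1 over (sample, label) pairs."""
    inter = len(y_pred_set & y_true_set)
    precision = inter / len(y_pred_set) if y_pred_set else 0.0
    recall = inter / len(y_true_set) if y_true_set else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def _pair_sets(y_pred, y_true, cls) -> tuple[set, set]:
    pred = {(i, cls) for i, v in enumerate(y_pred) if v == cls}
    true = {(i, cls) for i, v in enumerate(y_true) if v == cls}
    return pred, true


def per_class_prf(y_pred, y_true, classes) -> dict[str, tuple[float, float, float]]:
    return {
        cls: precision_recall_f1(*_pair_sets(y_pred, y_true, cls))
        for cls in classes
    }


def macro_f1(y_pred, y_true, classes=None, weighted: bool = False) -> float:
    """Mean per-class F1; unweighted by default, support-weighted optionally."""
    if classes is None:
        classes = sorted(set(y_true))
    if len(classes) == 0:
        raise ValueError("at least one class required")
    scores = per_class_prf(y_pred, y_true, classes)
    f1s = np.array([scores[c][2] for c in classes])
    if not weighted:
        return float(f1s.mean())
    support = np.array([sum(1 for v in y_true if v == c) for c in classes], dtype=float)
    if support.sum() == 0:
        return 0.0
    return float((f1s * support).sum() / support.sum())


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    """C[k, l] = number of samples of true class k predicted as class l."""
    index = {c: i for i, c in enumerate(classes)}
    C = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        C[index[t], index[p]] += 1
    return C


def mcc_multiclass(C: np.ndarray) -> float:
    """Generalized (Gorodkin) Matthews correlation from a confusion matrix."""
    C = np.asarray(C, dtype=float)
    if C.sum() < 1:
        raise ValueError("confusion matrix is empty")
    t = C.sum(axis=1)       # true-class totals
    p = C.sum(axis=0)       # predicted-class totals
    s = C.sum()
    c = np.trace(C)
    num = c * s - p @ t
    den = np.sqrt(s**2 - p @ p) * np.sqrt(s**2 - t @ t)
    if den == 0:
        return 0.0
    return float(num / den)


def one_vs_rest(y, positive_class) -> np.ndarray:
    """Indicator relabeling: the class in question becomes 1, the rest 0."""
    return np.asarray([1 if v == positive_class else 0 for v in y], dtype=int)


def average_precision(scores, labels) -> float:
    """AP = sum_n (recall_n - recall_{n-1}) * precision_n over descending
    score thresholds, one per distinct score (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("at least one positive label required")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted)
    n_pred = np.arange(1, len(scores) + 1)
    # Threshold boundaries: last position of each tied-score group.
    boundary = np.append(s_sorted[1:] != s_sorted[:-1], True)
    tp_b = tp[boundary]
    n_b = n_pred[boundary]
    precision = tp_b / n_b
    recall = tp_b / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev_recall) * precision).sum())


def orient_scores(scores, higher_is_positive: bool) -> np.ndarray:
    """Flip inverted score conventions: returns 1 - s when needed."""
    scores = np.asarray(scores, dtype=float)
    return scores if higher_is_positive else 1.0 - scores


def evaluation_report(y_true, probabilities: np.ndarray, classes) -> dict:
    """Per-class one-vs-rest AP and F1, plus macro-F1 and multiclass MCC.

    ``probabilities`` has one column per class in ``classes`` order;
    predicted labels are the argmax.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    y_pred = [classes[i] for i in probabilities.argmax(axis=1)]
    report = {"per_class": {}}
    for j, cls in enumerate(classes):
        binary = one_vs_rest(y_true, cls)
        prf = per_class_prf(y_pred, y_true, [cls])[cls]
        entry = {"precision": prf[0], "recall": prf[1], "f1": prf[2]}
        if binary.sum() > 0:
            entry["average_precision"] = average_precision(probabilities[:, j], binary)
        report["per_class"][cls] = entry
    report["macro_f1"] = macro_f1(y_pred, y_true, classes)
    report["mcc"] = mcc_multiclass(confusion_matrix(y_true, y_pred, classes))
    return report
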