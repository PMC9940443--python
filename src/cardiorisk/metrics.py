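"""Confusion-matrix metrics and one-vs-rest ROC-AUC.

Macro averaging (the unweighted mean of per-class precision/recall/F1) is
used throughout; a per-class metric with a zero denominator is defined as 0
with a warning.  The report can be built either from label sequences or
directly from a printed confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class MetricReport:
    """Confusion matrix (rows = true, cols = predicted) and derived scores."""

    labels: tuple
    confusion: np.ndarray
    accuracy: float
    precision: dict
    recall: dict
    f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @classmethod
    def from_confusion(cls, matrix, labels) -> "MetricReport":
        m = np.asarray(matrix, dtype=float)
        labels = tuple(labels)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(labels):
            raise InvalidInputError("confusion matrix must be square over labels")
        if np.any(m < 0):
            raise InvalidInputError("confusion-matrix cells must be >= 0")
        total = m.sum()
        if total == 0:
            raise InvalidInputError("empty confusion matrix")
        accuracy = float(np.trace(m) / total)
        precision, recall, f1 = {}, {}, {}
        for i, lab in enumerate(labels):
            col = m[:, i].sum()
            row = m[i, :].sum()
            if col == 0:
                warnings.warn(f"no predictions for class {lab!r}; precision := 0",
                              stacklevel=2)
            if row == 0:
                warnings.warn(f"no true instances of class {lab!r}; recall := 0",
                              stacklevel=2)
            p = m[i, i] / col if col else 0.0
            r = m[i, i] / row if row else 0.0
            precision[lab] = float(p)
            recall[lab] = float(r)
            f1[lab] = float(2 * p * r / (p + r)) if (p + r) else 0.0
        return cls(
            labels=labels,
            confusion=m,
            accuracy=accuracy,
            precision=precision,
            recall=recall,
            f1=f1,
            macro_precision=float(np.mean(list(precision.values()))),
            macro_recall=float(np.mean(list(recall.values()))),
            macro_f1=float(np.mean(list(f1.values()))),
        )

    @classmethod
    def from_predictions(cls, y_pred, y_true, labels=None) -> "MetricReport":
        y_pred = np.asarray(y_pred)
        y_true = np.asarray(y_true)
        if y_pred.shape != y_true.shape:
            raise InvalidInputError("prediction and truth lengths differ")
        if labels is None:
            labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
        labels = tuple(labels)
        index = {lab: i for i, lab in enumerate(labels)}
        outside = [v for v in set(y_true.tolist()) | set(y_pred.tolist())
                   if v not in index]
        if outside:
            raise InvalidInputError(f"label(s) outside the class set: {outside}")
        m = np.zeros((len(labels), len(labels)))
        for t, p in zip(y_true, y_pred):
            m[index[t], index[p]] += 1
        return cls.from_confusion(m, labels)

    def summary(self) -> str:
        lines = [
            f"n = {self.n}    accuracy = {self.accuracy:.4f}",
            f"macro precision = {self.macro_precision:.4f}  "
            f"recall = {self.macro_recall:.4f}  F1 = {self.macro_f1:.4f}",
            "class      precision  recall     F1",
        ]
        for lab in self.labels:
            lines.append(
                f"{str(lab):<10} {self.precision[lab]:<10.4f} "
                f"{self.recall[lab]:<10.4f} {self.f1[lab]:.4f}"
            )
        return "\n".join(lines)


def evaluate_classifier(predictions, truth, labels=None) -> MetricReport:
    """Build a `MetricReport` from predicted and true label sequences."""
    return MetricReport.from_predictions(predictions, truth, labels=labels)


def roc_auc_report(probabilities, truth, labels) -> dict:
    """One-vs-rest AUC per class via the rank-statistic (Mann-Whitney)
    formulation; a class absent from the truth gets ``nan``."""
    proba = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth)
    labels = tuple(labels)
    if proba.ndim != 2 or proba.shape[1] != len(labels):
        raise InvalidInputError("probability matrix must be n x n_classes")
    if proba.shape[0] != truth.shape[0]:
        raise InvalidInputError("probability and truth lengths differ")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise InvalidInputError("probability rows must sum to 1")
    out = {}
    for i, lab in enumerate(labels):
        pos = truth == lab
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[lab] = float("nan")
            continue
        scores = proba[:, i]
        # midrank-based Mann-Whitney statistic
        order = np.argsort(scores, kind="mergesort")
        ranks = np.empty(len(scores))
        sorted_scores = scores[order]
        ranks_sorted = np.arange(1, len(scores) + 1, dtype=float)
        # average ranks over ties
        start = 0
        for stop in range(1, len(scores) + 1):
            if stop == len(scores) or sorted_scores[stop] != sorted_scores[start]:
                ranks_sorted[start:stop] = ranks_sorted[start:stop].mean()
                start = stop
        ranks[order] = ranks_sorted
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        out[lab] = float(auc)
    return out
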