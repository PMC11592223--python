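"""Evaluation metrics: multi-class classification scores and MRE.

Accuracy, precision, recall and F1 follow the usual one-vs-rest reduction
of the binary TP/FP/FN/TN formulas (the only reduction consistent with
reporting per-class rows for a 3- or 4-class task).  Cohen's kappa
K = (p_o - p_e) / (1 - p_e) uses the observed agreement p_o (= accuracy)
and the chance agreement p_e = sum_c row_c * col_c / total^2.

For angle measurements the evaluation index is the mean relative error,
MRE = (1/N) * sum |measured_i - reference_i| / reference_i * 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, UndefinedMetricError


@dataclass
class ConfusionMatrix:
    """C x C counts, rows = actual class, columns = predicted class."""

    counts: np.ndarray
    class_labels: list

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
            raise DomainError("confusion matrix must be square and non-negative")
        if c.sum() == 0:
            raise DomainError("confusion matrix must contain at least one count")
        if len(self.class_labels) != c.shape[0]:
            raise DomainError("class_labels length must match matrix size")
        self.counts = c.astype(np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassScores:
    precision: float  # NaN when undefined
    recall: float
    f1: float
    defined: bool


@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict = field(default_factory=dict)
    kappa: float = 0.0
    p_o: float = 0.0
    p_e: float = 0.0
    macro_precision: float = float("nan")
    macro_recall: float = float("nan")
    macro_f1: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "p_o": self.p_o,
            "p_e": self.p_e,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                str(k): {
                    "precision": v.precision,
                    "recall": v.recall,
                    "f1": v.f1,
                    "defined": v.defined,
                }
                for k, v in self.per_class.items()
            },
        }


def confusion(actual, predicted, class_labels=None) -> ConfusionMatrix:
    """Tabulate actual vs predicted labels.

    ``class_labels`` declares the class set (defaults to the sorted labels
    seen); declared classes with no instances appear as zero rows/columns,
    and labels outside the declared set raise.
    """
    a = list(actual)
    p = list(predicted)
    if len(a) != len(p) or len(a) == 0:
        raise DomainError("actual and predicted must have equal nonzero length")
    labels = list(class_labels) if class_labels is not None else sorted(set(a) | set(p))
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for ai, pi in zip(a, p):
        if ai not in index or pi not in index:
            raise DomainError(f"label {ai if ai not in index else pi!r} not in declared class set")
        counts[index[ai], index[pi]] += 1
    return ConfusionMatrix(counts=counts, class_labels=labels)


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, one-vs-rest precision/recall/F1 per class, and Cohen's kappa.

    A class with zero actual *and* zero predicted instances has undefined
    precision and recall; it is flagged (NaN scores, ``defined=False``) and
    excluded from the macro averages rather than silently coerced to zero.
    """
    c = cm.counts.astype(float)
    total = c.sum()
    diag = np.diag(c)
    row = c.sum(axis=1)  # actual totals
    col = c.sum(axis=0)  # predicted totals

    p_o = float(diag.sum() / total)
    p_e = float((row * col).sum() / total**2)
    kappa = float((p_o - p_e) / (1.0 - p_e)) if p_e != 1.0 else 1.0

    per_class: dict = {}
    for i, lab in enumerate(cm.class_labels):
        tp = diag[i]
        fp = col[i] - tp
        fn = row[i] - tp
        if row[i] == 0 and col[i] == 0:
            per_class[lab] = ClassScores(float("nan"), float("nan"), float("nan"), False)
            continue
        prec = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
        rec = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        if np.isnan(prec) or np.isnan(rec) or (prec + rec) == 0:
            f1 = float("nan") if (np.isnan(prec) or np.isnan(rec)) else 0.0
        else:
            f1 = 2.0 * prec * rec / (prec + rec)
        per_class[lab] = ClassScores(float(prec), float(rec), float(f1), True)

    def macro(attr):
        vals = [getattr(s, attr) for s in per_class.values() if not np.isnan(getattr(s, attr))]
        return float(np.mean(vals)) if vals else float("nan")

    return MetricsReport(
        accuracy=p_o,
        per_class=per_class,
        kappa=kappa,
        p_o=p_o,
        p_e=p_e,
        macro_precision=macro("precision"),
        macro_recall=macro("recall"),
        macro_f1=macro("f1"),
    )


def mean_relative_error(measured, reference) -> float:
    """MRE in percent: mean of |measured - reference| / reference * 100.

    ``reference`` holds the ground-truth (clinician-annotated) values and
    must be nonzero everywhere; a zero reference raises naming its index.
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.ndim != 1 or len(m) == 0:
        raise DomainError("measured and reference must be equal-length 1-D sequences")
    zero = np.nonzero(r == 0)[0]
    if len(zero):
        raise UndefinedMetricError(f"reference value at index {zero[0]} is zero")
    return float(np.mean(np.abs(m - r) / np.abs(r)) * 100.0)
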