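"""Confusion-matrix metrics for imbalanced classification.

Accuracy is misleading when one class dominates, so evaluation here uses
chance-corrected and class-sensitive scores: Cohen's kappa, the Matthews
correlation coefficient (MCC), F1, precision and recall. All five derive
from the confusion matrix; kappa compares the observed agreement p_o with
the agreement p_e expected from the marginals alone,

    kappa = (p_o - p_e) / (1 - p_e),
    p_o   = (TP + TN) / total,
    p_e   = [(TP+FP)(TP+FN) + (TN+FN)(TN+FP)] / total^2,

and MCC is the correlation between predicted and actual assignments,

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FN)(TN+FP)).

For m >= 3 classes, kappa uses the full-table marginals, MCC uses the
multi-class correlation generalization (which reduces exactly to the
binary formula at m = 2), and precision/recall/F1 are macro-averaged
one-vs-rest values. Zero denominators yield 0 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ConfusionMatrix", "MetricReport", "confusion", "binary_metrics", "multiclass_metrics"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table; rows are actual classes, columns predicted."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.class_order):
            raise ValueError("class_order length must match matrix size")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_order", tuple(str(c) for c in self.class_order))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricReport:
    """Kappa, MCC, F1, precision and recall from one confusion matrix."""

    kappa: float
    mcc: float
    f1: float
    precision: float
    recall: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def as_row(self) -> list[float]:
        """CSV row order used by the evaluation harness."""
        return [self.kappa, self.mcc, self.f1, self.precision, self.recall]


def confusion(actual, predicted, class_order) -> ConfusionMatrix:
    """counts[i, j] = number of samples with actual class i predicted as class j."""
    actual = np.asarray(actual).astype(str)
    predicted = np.asarray(predicted).astype(str)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    order = tuple(str(c) for c in class_order)
    index = {c: i for i, c in enumerate(order)}
    unknown = set(actual) | set(predicted)
    unknown -= set(order)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in class_order")
    m = len(order)
    counts = np.zeros((m, m), dtype=int)
    for a, p in zip(actual, predicted):
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=order)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def binary_metrics(cm: ConfusionMatrix, positive: str) -> MetricReport:
    """The five scores for a 2x2 table with the given positive class."""
    if len(cm.class_order) != 2:
        raise ValueError("binary_metrics needs a 2x2 confusion matrix")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    positive = str(positive)
    if positive not in cm.class_order:
        raise ValueError(f"positive class {positive!r} not in {cm.class_order}")
    p = cm.class_order.index(positive)
    n = 1 - p
    tp = float(cm.counts[p, p])
    tn = float(cm.counts[n, n])
    fp = float(cm.counts[n, p])
    fn = float(cm.counts[p, n])
    total = tp + tn + fp + fn

    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    mcc = _safe_div(
        tp * tn - fp * fn,
        float(np.sqrt((tp + fp) * (tp + fn) * (tn + fn) * (tn + fp))),
    )
    p_o = (tn + tp) / total
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / total**2
    kappa = _safe_div(p_o - p_e, 1 - p_e)
    return MetricReport(kappa=kappa, mcc=mcc, f1=f1, precision=precision, recall=recall)


def multiclass_metrics(cm: ConfusionMatrix, averaging: str = "macro") -> MetricReport:
    """Macro-averaged precision/recall/F1 with full-table kappa and MCC.

    A 2x2 input falls back to :func:`binary_metrics` with the second
    class of ``class_order`` as positive, so binary tables score
    identically through either entry point.
    """
    if averaging != "macro":
        raise ValueError(f"unsupported averaging {averaging!r}")
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    m = len(cm.class_order)
    if m < 2:
        raise ValueError("need at least 2 classes")
    if m == 2:
        return binary_metrics(cm, positive=cm.class_order[1])

    counts = cm.counts.astype(float)
    total = counts.sum()
    diag = np.diag(counts)
    pred_marg = counts.sum(axis=0)  # column sums: predicted counts per class
    true_marg = counts.sum(axis=1)  # row sums: actual counts per class

    precisions = [_safe_div(diag[i], pred_marg[i]) for i in range(m)]
    recalls = [_safe_div(diag[i], true_marg[i]) for i in range(m)]
    f1s = [_safe_div(2 * p * r, p + r) for p, r in zip(precisions, recalls)]

    p_o = diag.sum() / total
    p_e = float(true_marg @ pred_marg) / total**2
    kappa = _safe_div(p_o - p_e, 1 - p_e)

    # multi-class MCC (R_K correlation); equals the 2x2 formula at m = 2
    c = diag.sum()
    num = c * total - float(true_marg @ pred_marg)
    den = float(
        np.sqrt(total**2 - pred_marg @ pred_marg) * np.sqrt(total**2 - true_marg @ true_marg)
    )
    mcc = _safe_div(num, den)

    return MetricReport(
        kappa=kappa,
        mcc=mcc,
        f1=float(np.mean(f1s)),
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
    )
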