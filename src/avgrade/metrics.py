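"""Classification metrics: confusion matrices, precision/recall, Cohen's kappa.

Cohen's kappa corrects raw agreement for chance:

    kappa = (p_o - p_e) / (1 - p_e)

with observed agreement ``p_o = trace / n`` and expected-by-chance agreement
``p_e = sum_i row_i * col_i / n^2``.  When both raters are degenerate
(``p_e = 1``) the statistic is defined here as 1 for perfect agreement and 0
otherwise.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np


def confusion_matrix(truth, pred, n_classes: int) -> np.ndarray:
    """L x L count matrix with rows = truth, columns = prediction."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size and (
        truth.min() < 0 or truth.max() >= n_classes or pred.min() < 0 or pred.max() >= n_classes
    ):
        raise ValueError(f"labels out of range [0, {n_classes})")
    out = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(out, (truth, pred), 1)
    return out


def cohen_kappa(confusion: np.ndarray) -> float:
    confusion = np.asarray(confusion, dtype=float)
    n = confusion.sum()
    if n < 1:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(confusion) / n
    p_e = float((confusion.sum(axis=1) * confusion.sum(axis=0)).sum()) / n**2
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if abs(1.0 - p_o) < 1e-15 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def precision_recall(confusion: np.ndarray, positive_class: int) -> tuple[float, float]:
    """Precision and recall for one class, with NaN for empty denominators.

    A zero denominator (no predicted positives for precision, no actual
    positives for recall) yields NaN and a warning; recall with FN > 0 but
    TP = 0 is simply 0.
    """
    confusion = np.asarray(confusion)
    L = confusion.shape[0]
    if not 0 <= positive_class < L:
        raise ValueError(f"positive_class {positive_class} out of range for L={L}")
    tp = confusion[positive_class, positive_class]
    fp = confusion[:, positive_class].sum() - tp
    fn = confusion[positive_class, :].sum() - tp
    if tp + fp == 0:
        warnings.warn(f"no predicted positives for class {positive_class}; precision undefined")
        precision = float("nan")
    else:
        precision = float(tp / (tp + fp))
    if tp + fn == 0:
        warnings.warn(f"no actual positives for class {positive_class}; recall undefined")
        recall = float("nan")
    else:
        recall = float(tp / (tp + fn))
    return precision, recall


@dataclasses.dataclass
class EvalReport:
    """Confusion matrix with its derived per-class and summary metrics."""

    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray  # per class
    macro_precision: float
    macro_recall: float
    kappa: float

    @classmethod
    def from_labels(cls, truth, pred, n_classes: int) -> "EvalReport":
        cm = confusion_matrix(truth, pred, n_classes)
        return cls.from_confusion(cm)

    @classmethod
    def from_confusion(cls, cm: np.ndarray) -> "EvalReport":
        n = cm.sum()
        L = cm.shape[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pr = [precision_recall(cm, k) for k in range(L)]
        precision = np.array([p for p, _ in pr])
        recall = np.array([r for _, r in pr])
        return cls(
            confusion=cm,
            accuracy=float(np.trace(cm) / n) if n else float("nan"),
            precision=precision,
            recall=recall,
            macro_precision=float(np.nanmean(precision)) if n else float("nan"),
            macro_recall=float(np.nanmean(recall)) if n else float("nan"),
            kappa=cohen_kappa(cm) if n else float("nan"),
        )

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "kappa": self.kappa,
        }
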