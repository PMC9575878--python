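"""Classification and feature-selection quality metrics.

F1 is always computed for the minority/positive class (label 1). The
feature-selection metrics compare a selected index set against the known
informative set of a simulated dataset: TPR_fs is the fraction of truly
informative features recovered, and the correct percentage treats the
selection as a per-feature binary decision and reports its accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score as _sk_f1

__all__ = [
    "SelectionMetrics",
    "f1_score",
    "tpr_fs",
    "correct_pct",
    "error_rate",
    "feature_reduction_pct",
    "f1_change",
]


@dataclass
class SelectionMetrics:
    f1: float
    error_rate: float
    tpr_fs: float
    correct_pct: float
    n_selected: int

    def __post_init__(self) -> None:
        if not 0 <= self.f1 <= 1:
            raise ValueError("f1 out of [0,1]")
        if not 0 <= self.error_rate <= 100:
            raise ValueError("error_rate out of [0,100]")
        if not 0 <= self.tpr_fs <= 1:
            raise ValueError("tpr_fs out of [0,1]")
        if not 0 <= self.correct_pct <= 100:
            raise ValueError("correct_pct out of [0,100]")


def f1_score(y_true, y_pred) -> float:
    """Minority-class F1 = 2PR/(P+R); 0 by convention when TP = 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return float(_sk_f1(y_true, y_pred, pos_label=1, zero_division=0))


def error_rate(y_true, y_pred) -> float:
    """Classification error as a percentage, 100·(1 − accuracy)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return float(100.0 * np.mean(y_true != y_pred))


def tpr_fs(selected, informative) -> float:
    """|selected ∩ informative| / |informative|."""
    informative = set(int(i) for i in informative)
    if not informative:
        raise ValueError("informative set must be non-empty")
    selected = set(int(i) for i in selected)
    return len(selected & informative) / len(informative)


def correct_pct(selected, informative, n: int) -> float:
    """Per-feature selection accuracy, as a percentage.

    Counts a true positive for each informative feature selected and a true
    negative for each noise feature left out: 100·(TP + TN)/n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    selected = set(int(i) for i in selected)
    informative = set(int(i) for i in informative)
    tp = len(selected & informative)
    tn = n - len(selected | informative)
    return 100.0 * (tp + tn) / n


def feature_reduction_pct(n_reference: int, n_selected: int, n_total: int) -> float:
    """Feature reduction (positive) or increment (negative) relative to a
    reference selection, as a percentage of the dataset's total feature count:
    100·(n_reference − n_selected)/n_total."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    return 100.0 * (n_reference - n_selected) / n_total


def f1_change(f1_reference: float, f1_new: float) -> float:
    """F1 increment (positive) or reduction (negative) over a reference."""
    return f1_new - f1_reference
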