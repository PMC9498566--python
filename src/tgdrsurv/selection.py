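"""Variable-importance extraction and selection accuracy metrics.

A fitted network does not expose per-variable effects directly; the
composite importance vector W12 = W2' W1 (one entry per input variable)
does, and a variable counts as selected iff its W12 entry is exactly
nonzero.  The exact-zero test is sound because TGDR leaves never-updated
weights bit-exactly zero.  For the linear Cox fit the coefficient vector
itself plays the role of W12.

Selection accuracy against a known truth is summarized by the confusion
counts, precision, recall, F1, and by the ROC/AUC of the selection path
traced across a sequence of tuning-parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .network import NetworkParams

__all__ = [
    "ImportanceVector",
    "SelectionMetrics",
    "importance",
    "selection_f1",
    "selection_roc",
    "selection_auc",
    "importance_table",
]


@dataclass
class ImportanceVector:
    """Per-variable importances w12 and the implied selection mask."""

    w12: np.ndarray
    selected: np.ndarray

    def __post_init__(self) -> None:
        self.w12 = np.asarray(self.w12, dtype=float).ravel()
        self.selected = np.asarray(self.selected, dtype=bool).ravel()
        if self.w12.size != self.selected.size:
            raise ValueError("w12 and selected must have equal length")


def importance(params: NetworkParams | np.ndarray) -> ImportanceVector:
    """W12 = W2' W1 for a network; the coefficients themselves for linear Cox."""
    if isinstance(params, NetworkParams):
        w12 = params.W2 @ params.W1
    else:
        w12 = np.asarray(params, dtype=float).ravel()
    return ImportanceVector(w12=w12, selected=w12 != 0.0)


@dataclass
class SelectionMetrics:
    """Confusion counts and derived accuracy of one selection."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float


def _as_mask(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.dtype != bool:
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
        arr = arr.astype(bool)
    return arr.ravel()


def selection_f1(selected, truth) -> SelectionMetrics:
    """Precision, recall and F1 = 2PR/(P+R) of a selection against the truth.

    Degenerate cases: precision is 0 when nothing is selected, and F1 is
    0 whenever there are no true positives.
    """
    sel = _as_mask(selected, "selected")
    tru = _as_mask(truth, "truth")
    if sel.size != tru.size:
        raise ValueError("selected and truth must have equal length")
    if not tru.any():
        raise ValueError("truth must contain at least one positive")
    tp = int(np.sum(sel & tru))
    fp = int(np.sum(sel & ~tru))
    tn = int(np.sum(~sel & ~tru))
    fn = int(np.sum(~sel & tru))
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn)
    f1 = 2 * precision * recall / (precision + recall) if tp > 0 else 0.0
    return SelectionMetrics(tp, fp, tn, fn, precision, recall, f1)


def selection_roc(
    selections: Sequence, truth
) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) points of a selection path, closed with (0,0) and (1,1).

    Each element of ``selections`` is a selection mask (or an
    :class:`ImportanceVector`) obtained at one tuning-parameter value.
    Points are returned sorted by FPR (then TPR).
    """
    if len(selections) == 0:
        raise ValueError("selection path is empty")
    tru = _as_mask(truth, "truth")
    n_pos = int(tru.sum())
    n_neg = tru.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain both positives and negatives")
    fpr = [0.0, 1.0]
    tpr = [0.0, 1.0]
    for sel in selections:
        if isinstance(sel, ImportanceVector):
            sel = sel.selected
        m = selection_f1(sel, tru)
        tpr.append(m.tp / n_pos)
        fpr.append(m.fp / n_neg)
    pts = sorted(zip(fpr, tpr))
    return np.array([q[0] for q in pts]), np.array([q[1] for q in pts])


def selection_auc(selections: Sequence, truth, fold: bool = True) -> float:
    """Trapezoid area under the selection ROC path.

    With ``fold=True`` (default) the area is reported on the [0.5, 1]
    convention as max(AUC, 1 - AUC); the raw trapezoid value is available
    with ``fold=False`` for diagnostics.
    """
    if len(selections) < 2:
        raise ValueError("need at least two grid points for a selection ROC")
    fpr, tpr = selection_roc(selections, truth)
    auc = float(np.trapezoid(tpr, fpr))
    return max(auc, 1.0 - auc) if fold else auc


def importance_table(
    imp: ImportanceVector, truth=None, feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Tidy per-variable table (id, w12, selected[, truth]) for CSV export."""
    p = imp.w12.size
    if feature_names is None:
        feature_names = [f"z{j + 1}" for j in range(p)]
    df = pd.DataFrame(
        {"variable": feature_names, "w12": imp.w12, "selected": imp.selected.astype(int)}
    )
    if truth is not None:
        df["truth"] = _as_mask(truth, "truth").astype(int)
    return df
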