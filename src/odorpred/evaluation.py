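"""Multi-label evaluation: per-label and macro-averaged metrics.

Conventions for degenerate cases: F1 is 0 when precision + recall = 0;
ROC-AUC and PR-AUC are undefined (NaN, with a warning) for a label whose
test column is single-class, and such labels are excluded from the macro
average rather than imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    hamming_loss,
    precision_recall_fscore_support,
    roc_auc_score,
)

from .containers import as_label_array, as_score_array


@dataclass
class LabelMetrics:
    """Per-label metrics plus multi-label aggregates."""

    per_label: pd.DataFrame  # index = label, columns incl. precision/recall/f1/roc_auc/pr_auc
    macro_f1: float
    macro_roc_auc: float
    macro_pr_auc: float
    hamming_loss: float
    subset_accuracy: float

    def to_dict(self) -> dict:
        return {
            "per_label": self.per_label.to_dict(orient="index"),
            "macro_f1": self.macro_f1,
            "macro_roc_auc": self.macro_roc_auc,
            "macro_pr_auc": self.macro_pr_auc,
            "hamming_loss": self.hamming_loss,
            "subset_accuracy": self.subset_accuracy,
        }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean F1 = 2PR/(P+R), defined as 0 when P + R = 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """F1 for one binary label (0 when no positives are predicted or present)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def macro_f1_score(truth, predictions) -> float:
    Y, P = as_label_array(truth), as_label_array(predictions)
    return float(np.mean([binary_f1(Y[:, k], P[:, k]) for k in range(Y.shape[1])]))


def compute_metrics(predictions, truth, scores=None, label_names=None) -> LabelMetrics:
    """Full multi-label metric panel.

    Parameters
    ----------
    predictions, truth : (n, K) binary matrices (arrays, DataFrames or
        LabelMatrix).
    scores : optional (n, K) probability matrix; required for the AUC
        members, which are reported as NaN without it.
    """
    P = as_label_array(predictions)
    Y = as_label_array(truth)
    if P.shape != Y.shape:
        raise ValueError(f"shape mismatch: predictions {P.shape} vs truth {Y.shape}")
    S = as_score_array(scores) if scores is not None else None
    if S is not None and S.shape != Y.shape:
        raise ValueError("score matrix shape mismatch")
    K = Y.shape[1]
    if label_names is None:
        label_names = getattr(truth, "label_names", None) or [f"label_{k}" for k in range(K)]

    prec, rec, f1, support = precision_recall_fscore_support(Y, P, average=None, zero_division=0)
    rows = []
    for k in range(K):
        roc = pr = np.nan
        single_class = Y[:, k].min() == Y[:, k].max()
        if S is not None:
            if single_class:
                warnings.warn(
                    f"label {label_names[k]!r} is single-class in truth; AUCs undefined"
                )
            else:
                roc = roc_auc_score(Y[:, k], S[:, k])
                pr = average_precision_score(Y[:, k], S[:, k])
        rows.append(
            dict(
                precision=prec[k],
                recall=rec[k],
                f1=f1[k],
                roc_auc=roc,
                pr_auc=pr,
                support=int(Y[:, k].sum()),
                positive_rate=float(Y[:, k].mean()),
            )
        )
    per_label = pd.DataFrame(rows, index=list(label_names))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN macro is a valid NaN
        macro_roc = float(np.nanmean(per_label["roc_auc"])) if S is not None else float("nan")
        macro_pr = float(np.nanmean(per_label["pr_auc"])) if S is not None else float("nan")
    return LabelMetrics(
        per_label=per_label,
        macro_f1=float(per_label["f1"].mean()),
        macro_roc_auc=macro_roc,
        macro_pr_auc=macro_pr,
        hamming_loss=float(hamming_loss(Y, P)),
        subset_accuracy=float(accuracy_score(Y, P)),
    )
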