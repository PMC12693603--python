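"""Per-label decision-threshold calibration.

Multi-label classifiers trained under heavy class imbalance tend to score
positives conservatively, so the default 0.5 cutoff starves recall.  For
each label independently, the calibrator sweeps a fixed grid of
thresholds over *validation* scores and keeps the one maximizing that
label's F1 (ties broken toward the smaller threshold, which favors
recall).  The calibrated thresholds are then applied unchanged at
inference.  The gain report is plain before/after arithmetic: absolute
gain = after − before, relative gain = 100·(after − before)/before.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import as_label_array, as_score_array
from .evaluation import binary_f1

DEFAULT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass
class ThresholdVector:
    """Per-label thresholds with the validation F1 achieved at each."""

    thresholds: np.ndarray
    f1_at_threshold: np.ndarray
    label_names: list[str]
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())

    def to_dict(self) -> dict:
        return {
            name: {"threshold": float(t), "f1": float(f)}
            for name, t, f in zip(self.label_names, self.thresholds, self.f1_at_threshold)
        }


class ThresholdCalibrator(BaseEstimator):
    """Sklearn-style calibrator: ``fit`` on validation scores/labels, then
    ``transform`` score matrices into binary predictions.

    Attributes (after fit)
    ----------------------
    thresholds_ : (K,) array of per-label cutoffs
    f1_at_threshold_ : (K,) validation F1 at each cutoff
    """

    def __init__(self, grid=None):
        self.grid = grid

    def fit(self, scores, labels, label_names=None):
        S = as_score_array(scores)
        Y = as_label_array(labels)
        if S.shape != Y.shape:
            raise ValueError("scores and labels must be row-aligned")
        grid = DEFAULT_GRID if self.grid is None else np.asarray(self.grid, dtype=float)
        if grid.size == 0:
            raise ValueError("threshold grid is empty")
        K = Y.shape[1]
        thresholds = np.empty(K)
        best_f1 = np.empty(K)
        for k in range(K):
            if Y[:, k].sum() == 0:
                warnings.warn(f"label {k} has no validation positives; threshold fixed at 0.5")
                thresholds[k], best_f1[k] = 0.5, 0.0
                continue
            f1s = np.array([binary_f1(Y[:, k], S[:, k] >= t) for t in grid])
            best = int(np.argmax(f1s))  # argmax takes the first = smallest threshold
            thresholds[k], best_f1[k] = grid[best], f1s[best]
        self.thresholds_ = thresholds
        self.f1_at_threshold_ = best_f1
        self.label_names_ = list(label_names) if label_names is not None else [
            f"label_{k}" for k in range(K)
        ]
        self.grid_ = grid
        return self

    def transform(self, scores) -> np.ndarray:
        S = as_score_array(scores)
        if S.shape[1] != self.thresholds_.shape[0]:
            raise ValueError("score matrix width does not match fitted thresholds")
        return (S >= self.thresholds_[None, :]).astype(np.int64)

    def threshold_vector(self) -> ThresholdVector:
        return ThresholdVector(
            self.thresholds_.copy(), self.f1_at_threshold_.copy(), list(self.label_names_), self.grid_.copy()
        )


def optimize_thresholds(scores, labels, grid=None, label_names=None) -> ThresholdVector:
    """Grid-search the per-label F1-optimal thresholds on validation data."""
    cal = ThresholdCalibrator(grid=grid).fit(scores, labels, label_names=label_names)
    return cal.threshold_vector()


def apply_thresholds(scores, thresholds) -> np.ndarray:
    """Binarize scores: prediction is 1 iff score ≥ threshold (per label)."""
    t = thresholds.thresholds if isinstance(thresholds, ThresholdVector) else np.asarray(thresholds, float)
    S = as_score_array(scores)
    if S.shape[1] != t.shape[0]:
        raise ValueError("dimension mismatch between scores and thresholds")
    return (S >= t[None, :]).astype(np.int64)


def gain_report(before, after, names=None) -> pd.DataFrame:
    """Before/after F1 accounting.

    Parameters may be scalars or equal-length sequences of F1 values.
    Relative gain is reported in percent to one decimal; it is NaN when the
    before-F1 is 0.
    """
    b = np.atleast_1d(np.asarray(before, dtype=float))
    a = np.atleast_1d(np.asarray(after, dtype=float))
    if b.shape != a.shape:
        raise ValueError("before/after length mismatch")
    absolute = a - b
    with np.errstate(divide="ignore", invalid="ignore"):
        relative = np.where(b > 0, np.round(100.0 * absolute / b, 1), np.nan)
    if names is None:
        names = [f"model_{i}" for i in range(b.size)]
    return pd.DataFrame(
        {
            "before_f1": b,
            "after_f1": a,
            "absolute_gain": np.round(absolute, 4),
            "relative_gain_pct": relative,
        },
        index=list(names),
    )
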