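"""Light containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabelMatrix:
    """Binary multi-label annotations: molecules × K labels."""

    values: np.ndarray  # (n, K) of {0, 1}
    label_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("label matrix must be 2-D")
        if self.values.shape[1] != len(self.label_names):
            raise ValueError("label count mismatch with label_names")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("labels must be binary")

    @property
    def n_labels(self) -> int:
        return self.values.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Per-label positive rate."""
        return self.values.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.label_names)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class ScoreMatrix:
    """Predicted probabilities in [0, 1]: molecules × K labels."""

    values: np.ndarray
    label_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.label_names):
            raise ValueError("score matrix shape mismatch")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("scores must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.label_names)

    def __len__(self) -> int:
        return self.values.shape[0]


def as_label_array(labels) -> np.ndarray:
    """Coerce a LabelMatrix / DataFrame / array to an (n, K) int array."""
    if isinstance(labels, LabelMatrix):
        return labels.values
    if isinstance(labels, pd.DataFrame):
        return labels.to_numpy(dtype=np.int64)
    return np.asarray(labels, dtype=np.int64)


def as_score_array(scores) -> np.ndarray:
    if isinstance(scores, ScoreMatrix):
        return scores.values
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=np.float64)
    return np.asarray(scores, dtype=np.float64)
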