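"""Descriptor-based baseline learners under binary-relevance decomposition.

Six classical model families — random forest, RBF-kernel SVM, gradient
boosting, multilayer perceptron, XGBoost and LightGBM — each trained as K
independent binary classifiers (one per odor label) on a processed
descriptor table, with hyperparameters chosen by stratified
cross-validated grid search on F1.  The learner internals are delegated
to scikit-learn / xgboost / lightgbm; this module owns the multi-label
plumbing, the probability contract (scores in [0, 1]) and the degenerate-
label policy (a single-class training label is skipped with a warning and
scored at its prior).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .containers import as_label_array

MODEL_KINDS = ("rf", "svm_rbf", "gbdt", "mlp", "xgboost", "lightgbm")

#: small default grids (≤ 12 points) per model family
DEFAULT_GRIDS = {
    "rf": {"n_estimators": [100, 300], "max_depth": [None, 8, 16]},
    "svm_rbf": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
    "gbdt": {"n_estimators": [100, 200], "learning_rate": [0.05, 0.1], "max_depth": [2, 3]},
    "mlp": {"hidden_layer_sizes": [(64,), (64, 32)], "alpha": [1e-4, 1e-3]},
    "xgboost": {"n_estimators": [100, 200], "max_depth": [3, 5], "learning_rate": [0.05, 0.1]},
    "lightgbm": {"n_estimators": [100, 200], "num_leaves": [15, 31], "learning_rate": [0.05, 0.1]},
}


@dataclass
class BaselineSpec:
    """Model family + hyperparameter grid + CV protocol (F1-scored)."""

    model_kind: str
    grid: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.model_kind].items()}
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be ≥ 2")


def _make_base(kind: str, seed: int):
    if kind == "rf":
        return RandomForestClassifier(random_state=seed)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if kind == "gbdt":
        return GradientBoostingClassifier(random_state=seed)
    if kind == "mlp":
        return MLPClassifier(max_iter=500, random_state=seed)
    if kind == "xgboost":
        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", tree_method="hist"
        )
    if kind == "lightgbm":
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, deterministic=True)
    raise ValueError(kind)


class _PriorScorer:
    """Fallback scorer for a degenerate label: constant prior probability."""

    def __init__(self, prior: float):
        self.prior = float(prior)

    def predict_proba(self, X):
        p = np.full((len(X), 2), 0.0)
        p[:, 1] = self.prior
        p[:, 0] = 1.0 - self.prior
        return p


class BinaryRelevanceClassifier(BaseEstimator, ClassifierMixin):
    """One grid-searched binary classifier per label.

    Fitted attributes: ``estimators_`` (per-label fitted scorers),
    ``best_params_`` (per-label winning grid point), ``label_names_``.
    """

    def __init__(self, model_kind: str = "rf", grid: dict | None = None,
                 cv_folds: int = 5, seed: int = 0):
        self.model_kind = model_kind
        self.grid = grid
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X, Y, label_names=None):
        spec = BaselineSpec(self.model_kind, dict(self.grid or {}), self.cv_folds, self.seed)
        X = np.asarray(X, dtype=float)
        Yv = as_label_array(Y)
        if X.shape[0] != Yv.shape[0]:
            raise ValueError("X and labels must be row-aligned")
        if label_names is None:
            label_names = getattr(Y, "label_names", None) or [f"label_{k}" for k in range(Yv.shape[1])]
        self.estimators_, self.best_params_ = [], []
        for k in range(Yv.shape[1]):
            y = Yv[:, k]
            if y.min() == y.max():
                warnings.warn(f"label {label_names[k]!r} single-class; scored at its prior")
                self.estimators_.append(_PriorScorer(y.mean()))
                self.best_params_.append(None)
                continue
            folds = min(spec.cv_folds, int(y.sum()), int((1 - y).sum()))
            base = _make_base(spec.model_kind, spec.seed)
            if folds >= 2:
                cv = StratifiedKFold(folds, shuffle=True, random_state=spec.seed)
                search = GridSearchCV(base, spec.grid, scoring="f1", cv=cv, n_jobs=1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    search.fit(X, y)
                self.estimators_.append(search.best_estimator_)
                self.best_params_.append(search.best_params_)
            else:
                base.fit(X, y)
                self.estimators_.append(base)
                self.best_params_.append(None)
        self.label_names_ = list(label_names)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n, K) matrix of positive-class probabilities."""
        X = np.asarray(X, dtype=float)
        cols = [est.predict_proba(X)[:, 1] for est in self.estimators_]
        return np.clip(np.column_stack(cols), 0.0, 1.0)

    def predict(self, X, thresholds=None) -> np.ndarray:
        S = self.predict_proba(X)
        t = np.full(S.shape[1], 0.5) if thresholds is None else np.asarray(thresholds, float)
        return (S >= t[None, :]).astype(np.int64)


def train_baselines(X_train, Y_train, spec: BaselineSpec, X_eval=None, label_names=None):
    """Fit one binary classifier per label; optionally score evaluation rows.

    Returns (fitted BinaryRelevanceClassifier, score matrix for X_eval or
    X_train when X_eval is None).
    """
    clf = BinaryRelevanceClassifier(
        model_kind=spec.model_kind, grid=spec.grid, cv_folds=spec.cv_folds, seed=spec.seed
    ).fit(X_train, Y_train, label_names=label_names)
    scores = clf.predict_proba(X_train if X_eval is None else X_eval)
    return clf, scores
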