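"""Descriptor-table processing: cleaning, feature selection, reduction.

Three composable strategies for molecular descriptor tables (molecules ×
numeric descriptors, missing values allowed):

* **Strategy A — basic preprocessing.**  Tiered missing-value handling
  (median imputation below 5% missing, 5-nearest-neighbour imputation at
  5–30%, column removal above 30%), IQR outlier clipping to
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR], then z-scoring.  All statistics come from
  training rows only and are reused verbatim for validation/test rows.
* **Strategy B — feature selection.**  On Strategy-A output: variance
  filter (τ = 0.01), global pairwise correlation filter (|ρ| > 0.95,
  dropping the later column of a violating pair), per-label mutual-
  information ranking (k-NN estimator, top-64 candidates), and recursive
  feature elimination with an L2 logistic model, choosing the subset size
  over a 12–33 grid by 5-fold cross-validated F1.
* **Strategy C — dimensionality reduction.**  PCA or RBF kernel PCA
  keeping the smallest number of components whose cumulative (eigen)
  variance reaches 0.95.

Quartiles and percentiles use linear interpolation throughout (the
common "type 7" convention); clip bounds depend on it, so it is frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA, KernelPCA
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .containers import as_label_array


@dataclass
class PreprocessReport:
    """Book-keeping of Strategy A: every input column appears exactly once."""

    columns: dict = field(default_factory=dict)
    # per column: {missing_rate, method ('median'|'knn'|'dropped'|'dropped_constant'),
    #              clip_lo, clip_hi, mu, sigma}

    def to_dict(self) -> dict:
        return self.columns


class StrategyAPreprocessor(BaseEstimator, TransformerMixin):
    """Tiered imputation → IQR clipping → standardization.

    Parameters
    ----------
    low_missing, high_missing : tier boundaries on the column missing rate
        (defaults 0.05 and 0.30).
    knn : neighbours used for moderate-missingness imputation.  Distances
        are Euclidean over median-pre-imputed copies of the training rows
        (pre-imputation breaks the circular dependence of distance on the
        values being imputed); the imputed value is the mean of the k
        nearest training rows that actually observed the column.
    """

    def __init__(self, low_missing: float = 0.05, high_missing: float = 0.30, knn: int = 5):
        self.low_missing = low_missing
        self.high_missing = high_missing
        self.knn = knn

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if len(X) < 2:
            raise ValueError("need at least 2 rows to fit")
        report = PreprocessReport()
        keep, methods, medians = [], {}, {}
        for c in X.columns:
            col = X[c].to_numpy(dtype=float)
            rate = float(np.isnan(col).mean())
            if rate > self.high_missing:
                report.columns[c] = {"missing_rate": rate, "method": "dropped"}
                continue
            methods[c] = "median" if rate < self.low_missing else "knn"
            med = np.nanmedian(col)
            medians[c] = float(med) if np.isfinite(med) else 0.0
            keep.append(c)
            report.columns[c] = {"missing_rate": rate, "method": methods[c]}

        # training reference matrices for k-NN imputation
        raw = X[keep].to_numpy(dtype=float)
        med_vec = np.array([medians[c] for c in keep])
        pre = np.where(np.isnan(raw), med_vec[None, :], raw)

        imputed = self._impute(raw, pre, keep, methods, med_vec)

        clip_lo, clip_hi, mu, sigma, final = {}, {}, {}, {}, []
        for j, c in enumerate(keep):
            col = imputed[:, j]
            q1, q3 = np.percentile(col, [25, 75])  # linear-interpolation quartiles
            iqr = q3 - q1
            if iqr == 0:
                # degenerate rule (e.g. a sparse binary indicator): clipping to
                # [Q1, Q3] would collapse the column, so it is left unclipped
                lo, hi = -np.inf, np.inf
            else:
                lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            clipped = np.clip(col, lo, hi)
            m, s = clipped.mean(), clipped.std(ddof=0)
            if s == 0:
                warnings.warn(f"column {c!r} constant after clipping; dropped")
                report.columns[c] = {
                    "missing_rate": report.columns[c]["missing_rate"],
                    "method": "dropped_constant",
                }
                continue
            clip_lo[c], clip_hi[c], mu[c], sigma[c] = lo, hi, m, s
            report.columns[c].update(clip_lo=lo, clip_hi=hi, mu=m, sigma=s)
            final.append(c)

        self.columns_ = final
        self.methods_ = {c: methods[c] for c in final}
        self.medians_ = {c: medians[c] for c in keep}
        self.clip_lo_, self.clip_hi_ = clip_lo, clip_hi
        self.mu_, self.sigma_ = mu, sigma
        self.report_ = report
        self._train_raw = raw          # (n_train, len(keep)) with NaNs
        self._train_pre = pre          # median-pre-imputed copy
        self._keep = keep
        return self

    def _impute(self, raw, pre, cols, methods, med_vec):
        """Impute a raw matrix (aligned to `cols`) against the training pool."""
        out = pre.copy()
        knn_js = [j for j, c in enumerate(cols) if methods.get(c) == "knn"]
        if not knn_js:
            return out
        train_raw, train_pre = self._train_raw if hasattr(self, "_train_raw") else raw, (
            self._train_pre if hasattr(self, "_train_pre") else pre
        )
        for j in knn_js:
            miss_rows = np.flatnonzero(np.isnan(raw[:, j]))
            if miss_rows.size == 0:
                continue
            observed = np.flatnonzero(~np.isnan(train_raw[:, j]))
            if observed.size == 0:
                continue  # falls back to the median already in `out`
            pool = train_pre[observed]
            for i in miss_rows:
                d = np.sqrt(((pool - pre[i]) ** 2).sum(axis=1))
                nearest = observed[np.argsort(d, kind="stable")[: self.knn]]
                out[i, j] = train_raw[nearest, j].mean()
        return out

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        raw = X.reindex(columns=self._keep).to_numpy(dtype=float)
        med_vec = np.array([self.medians_[c] for c in self._keep])
        pre = np.where(np.isnan(raw), med_vec[None, :], raw)
        imputed = self._impute(raw, pre, self._keep, self.methods_, med_vec)
        out = {}
        for j, c in enumerate(self._keep):
            if c not in self.columns_:
                continue
            col = np.clip(imputed[:, j], self.clip_lo_[c], self.clip_hi_[c])
            out[c] = (col - self.mu_[c]) / self.sigma_[c]
        return pd.DataFrame(out, index=X.index)[self.columns_]


def preprocess_strategy_a(table: pd.DataFrame, train_idx=None):
    """Fit Strategy A on training rows and transform the whole table.

    Returns (transformed table, PreprocessReport).
    """
    table = pd.DataFrame(table)
    fit_rows = table if train_idx is None else table.iloc[train_idx]
    pre = StrategyAPreprocessor().fit(fit_rows)
    return pre.transform(table), pre.report_


class StrategyBSelector(BaseEstimator):
    """Four-stage per-label feature selection on a preprocessed table.

    Fitted attributes: ``support_`` (label → selected column list) and
    ``trace_`` (per-stage survivors for auditability).
    """

    def __init__(
        self,
        variance_threshold: float = 0.01,
        corr_threshold: float = 0.95,
        mi_cap: int = 64,
        mi_neighbors: int = 3,
        rfe_sizes=(12, 16, 20, 24, 28, 33),
        cv: int = 5,
        random_state: int = 0,
    ):
        self.variance_threshold = variance_threshold
        self.corr_threshold = corr_threshold
        self.mi_cap = mi_cap
        self.mi_neighbors = mi_neighbors
        self.rfe_sizes = rfe_sizes
        self.cv = cv
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, Y, label_names=None):
        X = pd.DataFrame(X)
        Yv = as_label_array(Y)
        if label_names is None:
            label_names = getattr(Y, "label_names", None) or [f"label_{k}" for k in range(Yv.shape[1])]

        # stage 1: variance filter (global)
        variances = X.var(axis=0, ddof=0)
        var_kept = [c for c in X.columns if variances[c] >= self.variance_threshold]

        # stage 2: correlation filter (global, left-to-right, drop the later column)
        corr_kept = self._correlation_filter(X[var_kept])

        trace = {"variance": list(var_kept), "correlation": list(corr_kept)}
        support = {}
        for k, name in enumerate(label_names):
            y = Yv[:, k]
            if y.min() == y.max():
                warnings.warn(f"label {name!r} is single-class; selection skipped")
                support[name] = []
                trace[name] = {"mi": [], "rfe": []}
                continue
            support[name], label_trace = self._select_for_label(X[corr_kept], y)
            trace[name] = label_trace
        self.support_ = support
        self.trace_ = trace
        self.label_names_ = list(label_names)
        return self

    def _correlation_filter(self, X: pd.DataFrame) -> list:
        cols = list(X.columns)
        if len(cols) < 2:
            return cols
        corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
        corr = np.nan_to_num(corr, nan=0.0)
        kept_idx: list[int] = []
        for j in range(len(cols)):
            if all(abs(corr[j, i]) <= self.corr_threshold for i in kept_idx):
                kept_idx.append(j)
        return [cols[j] for j in kept_idx]

    def _select_for_label(self, X: pd.DataFrame, y: np.ndarray):
        # stage 3: mutual-information ranking (k-NN estimator), keep top-M
        mi = mutual_info_classif(
            X.to_numpy(dtype=float), y, n_neighbors=self.mi_neighbors,
            random_state=self.random_state,
        )
        order = np.argsort(-mi, kind="stable")[: self.mi_cap]
        candidates = [X.columns[i] for i in sorted(order)]
        # stage 4: RFE with L2 logistic regression; a single elimination pass
        # yields a full ranking, then the subset size is chosen over the
        # target grid by cross-validated F1 (ties toward the smaller size)
        lr = LogisticRegression(max_iter=2000, random_state=self.random_state)
        ranking = self._rfe_ranking(X[candidates].to_numpy(dtype=float), y)
        ranked_cols = [candidates[i] for i in ranking]
        sizes = sorted({min(s, len(ranked_cols)) for s in self.rfe_sizes})
        cv = StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state)
        best_size, best_score = sizes[0], -np.inf
        for s in sizes:
            cols = ranked_cols[:s]
            scores = cross_val_score(lr, X[cols].to_numpy(dtype=float), y, cv=cv, scoring="f1")
            m = scores.mean()
            if m > best_score + 1e-12:
                best_score, best_size = m, s
        selected = ranked_cols[:best_size]
        return selected, {"mi": candidates, "rfe_ranking": ranked_cols, "rfe_size": best_size}

    def _rfe_ranking(self, X: np.ndarray, y: np.ndarray) -> list[int]:
        """Recursive elimination by |coefficient|; returns indices best-first."""
        lr = LogisticRegression(max_iter=2000, random_state=self.random_state)
        remaining = list(range(X.shape[1]))
        eliminated: list[int] = []
        while len(remaining) > 1:
            lr.fit(X[:, remaining], y)
            coefs = np.abs(lr.coef_[0])
            drop = int(np.argmin(coefs))  # first minimum → deterministic
            eliminated.append(remaining.pop(drop))
        return remaining + eliminated[::-1]


def select_features_strategy_b(table: pd.DataFrame, labels, **kwargs) -> dict:
    """Per-label selected column subsets (Strategy B)."""
    sel = StrategyBSelector(**kwargs).fit(table, labels)
    return sel.support_


class StrategyCReducer(BaseEstimator, TransformerMixin):
    """PCA / RBF-kernel-PCA keeping 95% cumulative (eigen)variance."""

    def __init__(self, method: str = "pca", variance_ratio: float = 0.95, random_state: int = 0):
        self.method = method
        self.variance_ratio = variance_ratio
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(pd.DataFrame(X), dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows")
        if self.method == "pca":
            self.model_ = PCA(n_components=self.variance_ratio, svd_solver="full").fit(X)
            self.n_components_ = int(self.model_.n_components_)
            ratios = self.model_.explained_variance_ratio_
        elif self.method == "kpca":
            full = KernelPCA(kernel="rbf", random_state=self.random_state).fit(X)
            lam = full.eigenvalues_
            cum = np.cumsum(lam) / lam.sum()
            self.n_components_ = int(np.searchsorted(cum, self.variance_ratio) + 1)
            self.model_ = KernelPCA(
                kernel="rbf", n_components=self.n_components_, random_state=self.random_state
            ).fit(X)
            ratios = lam[: self.n_components_] / lam.sum()
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.explained_ratio_ = np.asarray(ratios)[: self.n_components_]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(pd.DataFrame(X), dtype=float)
        return self.model_.transform(X)[:, : self.n_components_]


def reduce_strategy_c(table: pd.DataFrame, method: str = "pca", train_idx=None, **kwargs):
    """Fit the reducer on training rows and project the whole table."""
    table = pd.DataFrame(table)
    fit_rows = table if train_idx is None else table.iloc[train_idx]
    red = StrategyCReducer(method=method, **kwargs).fit(fit_rows)
    return red.transform(table), red
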