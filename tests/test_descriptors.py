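"""Strategies A/B/C: imputation tiers, clipping, selection, reduction."""

import numpy as np
import pandas as pd
import pytest

from odorpred.descriptors import (
    StrategyAPreprocessor,
    StrategyBSelector,
    StrategyCReducer,
    preprocess_strategy_a,
    select_features_strategy_b,
)
from odorpred.synthetic import (
    DEFAULT_RULE_TABLE,
    DescriptorNoiseSpec,
    GenerationConfig,
    make_dataset,
)


def _table(**cols):
    return pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in cols.items()})


class TestStrategyA:
    def test_iqr_clip_hand_computation(self):
        """[1,2,3,4,100]: Q1=2, Q3=4 (linear interpolation), upper bound 7."""
        pre = StrategyAPreprocessor().fit(_table(x=[1, 2, 3, 4, 100]))
        assert pre.clip_lo_["x"] == pytest.approx(2 - 3.0)
        assert pre.clip_hi_["x"] == pytest.approx(4 + 3.0)

    def test_high_missing_column_dropped(self):
        t = _table(a=[1, 2, 3, 4, 5], b=[1, np.nan, np.nan, 4, 5])  # 40% missing
        out, report = preprocess_strategy_a(t)
        assert "b" not in out.columns
        assert report.columns["b"]["method"] == "dropped"

    def test_survivors_are_zscored(self):
        rng = np.random.default_rng(0)
        t = _table(a=rng.normal(5, 3, 200), b=rng.exponential(2, 200))
        out, _ = preprocess_strategy_a(t)
        assert np.allclose(out.mean(), 0, atol=1e-9)
        assert np.allclose(out.std(ddof=0), 1, atol=1e-9)

    def test_median_vs_knn_tier_assignment(self):
        rng = np.random.default_rng(1)
        n = 200
        low = rng.normal(size=n)
        low[:4] = np.nan  # 2% → median tier
        mid = rng.normal(size=n)
        mid[:30] = np.nan  # 15% → knn tier
        _, report = preprocess_strategy_a(_table(low=low, mid=mid, anchor=rng.normal(size=n)))
        assert report.columns["low"]["method"] == "median"
        assert report.columns["mid"]["method"] == "knn"

    def test_knn_imputation_uses_similar_rows(self):
        # two clusters far apart; the missing cell should be filled from its
        # own cluster's values, not the global median
        n = 40
        a = np.concatenate([np.zeros(n), np.ones(n) * 100.0])
        b = np.concatenate([np.full(n, 5.0), np.full(n, 50.0)])
        b[np.arange(0, 2 * n, 7)] = np.nan  # ~14% missing → knn tier
        pre = StrategyAPreprocessor().fit(_table(a=a, b=b))
        raw = _table(a=a, b=b)
        out = pre.transform(raw)
        # row 0 (cluster 1, missing b) must match cluster-1's b value after scaling
        filled = out["b"].to_numpy()
        assert filled[0] == pytest.approx(filled[1], abs=1e-9)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        t = _table(a=rng.normal(0, 10, 300), b=rng.standard_t(3, 300))
        once, _ = preprocess_strategy_a(t)
        twice, _ = preprocess_strategy_a(once)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-9)

    def test_no_test_row_leakage(self):
        rng = np.random.default_rng(3)
        t = _table(a=rng.normal(size=100), b=rng.normal(size=100))
        train = np.arange(60)
        out1, _ = preprocess_strategy_a(t, train_idx=train)
        t2 = t.copy()
        t2.iloc[60:] = t2.iloc[60:] * 50 + 7  # mutate test rows only
        pre1 = StrategyAPreprocessor().fit(t.iloc[train])
        pre2 = StrategyAPreprocessor().fit(t2.iloc[train])
        assert pre1.mu_ == pre2.mu_ and pre1.sigma_ == pre2.sigma_
        assert pre1.clip_lo_ == pre2.clip_lo_ and pre1.clip_hi_ == pre2.clip_hi_
        np.testing.assert_array_equal(
            out1.iloc[:60].to_numpy(), pre2.transform(t2).iloc[:60].to_numpy()
        )

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out, report = preprocess_strategy_a(_table(c=[5, 5, 5, 5], a=[1, 2, 3, 4]))
        assert "c" not in out.columns
        assert report.columns["c"]["method"] == "dropped_constant"


class TestStrategyB:
    def _planted(self, seed=0):
        rules = {k: (s, 1.0, 0.0) for k, (s, _, _) in DEFAULT_RULE_TABLE.items()}
        cfg = GenerationConfig(n_molecules=250, seed=seed, rule_table=rules)
        smiles, labels, table = make_dataset(cfg, DescriptorNoiseSpec(n_descriptors=50))
        X, _ = preprocess_strategy_a(table)
        return X, labels

    def test_constant_and_duplicate_columns_removed(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=120)
        X = _table(a=base, dup=base.copy(), const=np.full(120, 0.5), b=rng.normal(size=120))
        y = (base > 0).astype(int).reshape(-1, 1)
        sel = StrategyBSelector(rfe_sizes=(2,), cv=3).fit(X, y)
        assert "const" not in sel.trace_["variance"]
        assert "dup" not in sel.trace_["correlation"] and "a" in sel.trace_["correlation"]

    def test_planted_column_recovered(self):
        X, labels = self._planted(seed=0)
        support = select_features_strategy_b(X, labels, random_state=0)
        assert "match_fruity" in support["fruity"]

    def test_single_class_label_skipped(self):
        rng = np.random.default_rng(5)
        X = _table(a=rng.normal(size=50), b=rng.normal(size=50))
        Y = np.zeros((50, 2), dtype=int)
        Y[:, 1] = (X["a"] > 0).astype(int)
        with pytest.warns(UserWarning, match="single-class"):
            sel = StrategyBSelector(rfe_sizes=(1,), cv=2).fit(X, Y)
        assert sel.support_["label_0"] == []

    def test_variance_pool_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        X = _table(**{f"c{i}": rng.normal(scale=0.05 * (i + 1), size=80) for i in range(10)})
        y = (X["c9"] > 0).astype(int).to_numpy().reshape(-1, 1)
        tight = StrategyBSelector(variance_threshold=0.01, rfe_sizes=(2,), cv=2).fit(X, y)
        loose = StrategyBSelector(variance_threshold=0.001, rfe_sizes=(2,), cv=2).fit(X, y)
        assert set(tight.trace_["variance"]) <= set(loose.trace_["variance"])

    def test_selected_width_bounded_by_mi_cap(self):
        X, labels = self._planted(seed=1)
        sel = StrategyBSelector(mi_cap=16, rfe_sizes=(4, 8), cv=3).fit(X, labels)
        for cols in sel.support_.values():
            assert len(cols) <= 16


class TestStrategyC:
    def test_rank2_data_needs_two_components(self):
        rng = np.random.default_rng(7)
        basis = rng.normal(size=(2, 10))
        X = rng.normal(size=(300, 2)) @ basis
        red = StrategyCReducer("pca").fit(X)
        assert red.n_components_ == 2

    def test_isotropic_gaussian_needs_all_components(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10000, 5))
        assert StrategyCReducer("pca").fit(X).n_components_ == 5

    def test_cumulative_variance_reaches_ratio(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 20)) * np.linspace(5, 0.1, 20)
        red = StrategyCReducer("pca").fit(X)
        assert red.explained_ratio_.sum() >= 0.95

    def test_kernel_pca_transforms_to_selected_width(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(80, 6))
        red = StrategyCReducer("kpca").fit(X)
        Z = red.transform(X[:10])
        assert Z.shape == (10, red.n_components_)

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            StrategyCReducer("pca").fit(np.ones((1, 3)))
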