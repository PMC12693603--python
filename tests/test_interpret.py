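"""Attribution: analytic gradients, attention aggregation, fragment
extraction and cross-method correlation."""

import numpy as np
import pytest

from odorpred.featurization import MolecularGraph, smiles_to_graph
from odorpred.gnn import GNNClassifier
from odorpred.interpret import (
    NodeImportance,
    aggregate_fragments,
    attention_node_importance,
    extract_fragments,
    fragment_report,
    gradient_node_importance,
    importance_correlation,
    load_smarts_library,
)


def _bare_model(arch, n_layers=1, hidden=4, heads=2, seed=0, n_labels=1):
    """An untrained model with directly settable weights (no BN/dropout)."""
    clf = GNNClassifier(architecture=arch, hidden_dim=hidden, n_layers=n_layers,
                        gat_heads=heads, batch_norm=False, dropout=0.0, seed=seed)
    clf._build(n_labels, np.random.default_rng(seed))
    clf.label_names_ = [f"l{k}" for k in range(n_labels)]
    return clf


def _fake_graph(node_features, edge_index, smiles="C"):
    x = np.asarray(node_features, dtype=float)
    ei = np.asarray(edge_index, dtype=np.int64).reshape(2, -1)
    ef = np.zeros((ei.shape[1], 6))
    ef[:, 0] = 1
    return MolecularGraph(x, ei, ef, smiles=smiles)


class TestGradientImportance:
    def test_zero_first_layer_weights_give_zero_importance(self):
        clf = _bare_model("gcn", hidden=1)
        clf.convs_[0].W.data[:] = 0.0
        clf.convs_[0].b.data[:] = 0.0
        g = smiles_to_graph("CCO")
        imp = gradient_node_importance(clf, g, 0)
        np.testing.assert_array_equal(imp.scores, 0.0)

    def test_linear_single_node_model_recovers_weight(self):
        """One node, one linear path: |∂logit/∂x_1| = |w|."""
        w = 1.7
        clf = _bare_model("gcn", hidden=1)
        clf.convs_[0].W.data[:] = 0.0
        clf.convs_[0].W.data[1, 0] = w
        clf.convs_[0].b.data[:] = 0.0
        clf.head_W1_.data[:] = 1.0
        clf.head_b1_.data[:] = 0.0
        clf.head_W2_.data[:] = 1.0
        clf.head_b2_.data[:] = 0.0
        x = np.zeros((1, 25))
        x[0, 1] = 2.0  # keeps every ReLU on the path active
        imp = gradient_node_importance(clf, _fake_graph(x, np.zeros((2, 0))), 0)
        assert imp.scores[0] == pytest.approx(w)

    def test_invariant_to_node_reordering(self, trained_gcn, small_graphs):
        g = small_graphs[3]
        perm = np.random.default_rng(0).permutation(g.n_nodes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        gp = MolecularGraph(g.node_features[perm], inv[g.edge_index],
                            g.edge_features.copy(), smiles=g.smiles)
        base = gradient_node_importance(trained_gcn, g, 0).scores
        permuted = gradient_node_importance(trained_gcn, gp, 0).scores
        np.testing.assert_allclose(permuted, base[perm], atol=1e-8)

    def test_label_index_out_of_range(self, trained_gcn, small_graphs):
        with pytest.raises(IndexError):
            gradient_node_importance(trained_gcn, small_graphs[0], 99)


class TestAttentionImportance:
    def _uniform_gat(self, n_layers=1):
        clf = _bare_model("gat", n_layers=n_layers)
        for conv in clf.convs_:
            conv.a_src.data[:] = 0.0  # equal logits → uniform attention
            conv.a_dst.data[:] = 0.0
        return clf

    def test_star_graph_center_importance(self):
        """Uniform attention, center with d=4 neighbours → I = d/(d+1)."""
        d = 4
        src = np.concatenate([np.zeros(d, int), np.arange(1, d + 1)])
        dst = np.concatenate([np.arange(1, d + 1), np.zeros(d, int)])
        g = _fake_graph(np.random.default_rng(1).normal(size=(d + 1, 25)),
                        np.stack([src, dst]))
        imp = attention_node_importance(self._uniform_gat(), g)
        assert imp.scores[0] == pytest.approx(d / (d + 1))
        np.testing.assert_allclose(imp.scores[1:], 0.5)  # leaves: {center, self}

    def test_single_node_importance_is_one(self):
        g = _fake_graph(np.ones((1, 25)), np.zeros((2, 0)))
        imp = attention_node_importance(self._uniform_gat(), g)
        assert imp.scores[0] == pytest.approx(1.0)

    def test_layer_count_normalization(self):
        src = np.array([0, 1])
        dst = np.array([1, 0])
        g = _fake_graph(np.random.default_rng(2).normal(size=(2, 25)), np.stack([src, dst]))
        one = attention_node_importance(self._uniform_gat(1), g).scores
        two = attention_node_importance(self._uniform_gat(2), g).scores
        np.testing.assert_allclose(one, two, atol=1e-12)

    def test_non_gat_model_raises(self, trained_gcn, small_graphs):
        with pytest.raises(ValueError):
            attention_node_importance(trained_gcn, small_graphs[0])


class TestFragments:
    def test_equal_importance_selects_whole_molecule(self):
        g = smiles_to_graph("CCCCO")
        recs = extract_fragments(g, NodeImportance(np.ones(g.n_nodes), "gradient"))
        assert len(recs) == 1
        assert sorted(recs[0].atom_indices) == list(range(g.n_nodes))

    def test_hexanal_hot_carbonyl_maps_to_aldehyde(self):
        g = smiles_to_graph("CCCCCC=O")
        scores = np.zeros(g.n_nodes)
        scores[5] = scores[6] = 1.0  # CHO carbon + oxygen
        recs = extract_fragments(g, NodeImportance(scores, "gradient"))
        assert len(recs) == 1
        assert recs[0].group == "aldehyde"

    def test_two_hot_regions_give_two_records(self):
        g = smiles_to_graph("OCCCCCO")
        scores = np.zeros(g.n_nodes)
        scores[0] = scores[6] = 1.0  # the two terminal oxygens
        recs = extract_fragments(g, NodeImportance(scores, "gradient"))
        assert len(recs) == 2

    def test_components_disjoint_and_connected_on_random_molecules(self, small_graphs):
        rng = np.random.default_rng(3)
        for g in small_graphs[:100]:
            scores = rng.uniform(size=g.n_nodes)
            recs = extract_fragments(g, NodeImportance(scores, "gradient"))
            seen = set()
            neighbors = {}
            for s, d in g.edge_index.T:
                neighbors.setdefault(int(s), set()).add(int(d))
            for rec in recs:
                atoms = set(rec.atom_indices)
                assert not atoms & seen  # disjoint
                seen |= atoms
                if len(atoms) > 1:  # connected: everyone reaches a co-member
                    for a in atoms:
                        assert neighbors.get(a, set()) & atoms

    def test_empty_graph_raises(self):
        g = _fake_graph(np.zeros((0, 25)), np.zeros((2, 0)))
        with pytest.raises(ValueError):
            extract_fragments(g, NodeImportance(np.zeros(0), "gradient"))

    def test_smarts_library_has_forty_plus_valid_patterns(self):
        lib = load_smarts_library()
        assert len(lib) >= 40
        names = [name for _, name, _ in lib]
        for expected in ("ester", "aldehyde", "ketone", "alcohol", "thiol"):
            assert expected in names


class TestAggregation:
    def test_single_molecule_single_fragment(self):
        g = smiles_to_graph("CCO")
        recs = extract_fragments(g, NodeImportance(np.ones(3), "gradient"))
        table = aggregate_fragments([recs])
        assert len(table) == 1
        assert table["count"].iloc[0] == 1

    def test_empty_input_warns_and_returns_empty_table(self):
        with pytest.warns(UserWarning, match="no fragment records"):
            table = aggregate_fragments([])
        assert table.empty

    def test_report_uses_only_correct_positive_predictions(self, trained_gcn, small_dataset, small_graphs):
        _, labels = small_dataset
        Y = labels.values[:60]
        P = np.zeros_like(Y)  # nothing predicted → nothing to attribute
        with pytest.warns(UserWarning):
            tables = fragment_report(trained_gcn, small_graphs[:60], Y, P,
                                     label_names=labels.label_names, n_samples=5)
        assert all(t.empty for t in tables.values())


class TestCorrelation:
    def test_identical_vectors_correlate_perfectly(self):
        a = NodeImportance([1.0, 2.0, 5.0, 3.0], "gradient")
        assert importance_correlation(a, a) == pytest.approx(1.0)

    def test_reversed_vector_is_anticorrelated(self):
        a = NodeImportance([1.0, 2.0, 3.0], "gradient")
        b = NodeImportance([10.0 - 1.0, 10.0 - 2.0, 10.0 - 3.0], "attention")
        assert importance_correlation(a, b) == pytest.approx(-1.0)

    def test_textbook_pearson_value(self):
        a = NodeImportance([1, 2, 3, 4, 5], "gradient")
        b = NodeImportance([2, 4, 5, 4, 5], "attention")
        assert importance_correlation(a, b) == pytest.approx(6 / np.sqrt(60), abs=1e-4)

    def test_zero_variance_returns_nan(self):
        a = NodeImportance([1.0, 1.0, 1.0], "gradient")
        b = NodeImportance([1.0, 2.0, 3.0], "attention")
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(importance_correlation(a, b))
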