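"""GNN layers (hand-computed propagation), losses, and training contracts."""

import numpy as np
import pytest

from odorpred._autodiff import Tensor
from odorpred.featurization import MolecularGraph, smiles_to_graph
from odorpred.gnn import (
    GATLayer,
    GNNClassifier,
    GNNConfig,
    GraphBatch,
    NNConvLayer,
    bce_loss,
    focal_loss,
    gat_layer,
    gcn_layer,
    nnconv_layer,
    train_gnn,
    weighted_bce_loss,
)


def _permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Renumber nodes: new node i carries old node perm[i]."""
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return MolecularGraph(
        node_features=g.node_features[perm],
        edge_index=inv[g.edge_index],
        edge_features=g.edge_features.copy(),
        smiles=g.smiles,
    )


class TestGCNLayer:
    def test_single_node_identity(self):
        x = np.array([[1.0, 2.0, 3.0]])
        out = gcn_layer(x, np.zeros((2, 0)), np.eye(3))
        np.testing.assert_allclose(out, x)  # self-loop coefficient is 1

    def test_two_node_symmetric_normalization(self):
        """d=1 on both ends: every coefficient is 1/√(2·2) = 1/2."""
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        edges = np.array([[0, 1], [1, 0]])
        out = gcn_layer(x, edges, np.eye(2))
        np.testing.assert_allclose(out, 0.5 * (x + x[::-1]))

    def test_node_permutation_equivariance(self):
        g = smiles_to_graph("CCC(=O)OC")
        rng = np.random.default_rng(0)
        W = rng.normal(size=(25, 8))
        perm = rng.permutation(g.n_nodes)
        gp = _permute_graph(g, perm)
        out = gcn_layer(g.node_features, g.edge_index, W)
        outp = gcn_layer(gp.node_features, gp.edge_index, W)
        np.testing.assert_allclose(outp, out[perm], atol=1e-12)


class TestGATLayer:
    def _layer(self, in_dim=4, out_dim=8, heads=2, seed=0):
        return GATLayer(np.random.default_rng(seed), in_dim, out_dim, heads)

    def test_attention_sums_to_one_per_neighborhood(self):
        g = smiles_to_graph("CC(=O)OCC")
        layer = self._layer(in_dim=25)
        _, att = gat_layer(g.node_features, g.edge_index, layer)
        sums = np.zeros((g.n_nodes, att["alpha"].shape[1]))
        np.add.at(sums, att["dst"], att["alpha"])
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_identical_features_give_uniform_attention(self):
        x = np.tile([[1.0, 2.0, 3.0, 4.0]], (3, 1))
        edges = np.array([[0, 1, 1, 2], [1, 0, 2, 1]])  # path 0-1-2
        _, att = gat_layer(x, edges, self._layer())
        # node 1 attends over {0, 2, self} → uniform 1/3
        at_node1 = att["alpha"][att["dst"] == 1]
        np.testing.assert_allclose(at_node1, 1.0 / 3.0, atol=1e-12)

    def test_single_node_self_attention_is_one(self):
        x = np.ones((1, 4))
        _, att = gat_layer(x, np.zeros((2, 0)), self._layer())
        np.testing.assert_allclose(att["alpha"], 1.0)


class TestNNConvLayer:
    def test_zero_edge_network_leaves_root_only(self):
        g = smiles_to_graph("CCO")
        layer = NNConvLayer(np.random.default_rng(1), 25, 6)
        for p in (layer.E1, layer.e1, layer.E2, layer.e2):
            p.data[:] = 0.0
        out = nnconv_layer(g.node_features, g.edge_index, g.edge_features, layer)
        root = g.node_features @ layer.W_root.data + layer.b.data
        np.testing.assert_allclose(out, root)

    def test_hand_set_edge_transform_matrix(self):
        """With Θ(e) ≡ M and zero root, the message is exactly M·h_src."""
        in_dim, out_dim = 3, 2
        M = np.array([[1.0, 2.0, -1.0], [0.5, 0.0, 3.0]])
        layer = NNConvLayer(np.random.default_rng(2), in_dim, out_dim, edge_dim=6)
        layer.E1.data[:] = 0.0
        layer.e1.data[:] = 0.0
        layer.E2.data[:] = 0.0
        layer.e2.data[:] = M.reshape(-1)
        layer.W_root.data[:] = 0.0
        x = np.array([[1.0, -1.0, 2.0], [0.0, 0.0, 0.0]])
        edges = np.array([[0], [1]])  # single directed edge 0 → 1
        ef = np.ones((1, 6))
        out = nnconv_layer(x, edges, ef, layer)
        np.testing.assert_allclose(out[1], M @ x[0])
        np.testing.assert_allclose(out[0], 0.0)

    def test_missing_edge_features_raise(self):
        layer = NNConvLayer(np.random.default_rng(3), 3, 2)
        with pytest.raises(ValueError):
            nnconv_layer(np.ones((2, 3)), np.array([[0], [1]]), np.ones((1, 2)), layer)

    def test_edge_order_invariance_with_symmetric_features(self):
        g = smiles_to_graph("CC=O")
        layer = NNConvLayer(np.random.default_rng(4), 25, 6)
        out = nnconv_layer(g.node_features, g.edge_index, g.edge_features, layer)
        order = np.arange(g.n_edges)[::-1]
        out2 = nnconv_layer(g.node_features, g.edge_index[:, order], g.edge_features[order], layer)
        np.testing.assert_allclose(out, out2, atol=1e-12)


class TestLosses:
    def test_focal_reduces_to_bce_at_gamma_zero(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.01, 0.99, size=(20, 6))
        y = rng.integers(0, 2, size=(20, 6))
        assert focal_loss(p, y, alpha=1.0, gamma=0.0) == pytest.approx(
            bce_loss(p, y), abs=1e-9
        )

    def test_single_term_hand_value(self):
        expected = 0.25 * 0.1**2 * (-np.log(0.9))
        assert focal_loss([[0.9]], [[1]], alpha=0.25, gamma=2.0) == pytest.approx(expected)

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        y = np.array([[1, 0], [0, 1]])
        p = np.where(y == 1, 1.0 - 1e-9, 1e-9)
        assert focal_loss(p, y, alpha=0.25, gamma=2.0) < 1e-6

    def test_extreme_scores_are_clamped_finite(self):
        assert np.isfinite(focal_loss([[0.0, 1.0]], [[1, 0]], alpha=0.5, gamma=2.0))

    def test_weighted_bce_equals_plain_under_balance(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.9, size=(10, 2))
        y = np.tile([[1, 0], [0, 1]], (5, 1))  # both labels exactly balanced
        n_pos = y.sum(axis=0)
        w = (len(y) - n_pos) / n_pos
        assert weighted_bce_loss(p, y, w) == pytest.approx(bce_loss(p, y))


class TestTrainedModel:
    def _tiny(self, labels, graphs, arch, seed=0, **kw):
        idx = np.arange(40)
        clf = GNNClassifier(
            architecture=arch, hidden_dim=16, n_layers=2, gat_heads=2,
            max_epochs=8, patience=8, seed=seed, **kw,
        )
        clf.fit(
            [graphs[i] for i in idx[:30]], labels.values[idx[:30]],
            validation_data=([graphs[i] for i in idx[30:]], labels.values[idx[30:]]),
        )
        return clf

    @pytest.mark.parametrize("arch", ["gcn", "gat", "nnconv"])
    def test_prediction_invariant_to_node_reordering(self, small_dataset, small_graphs, arch):
        _, labels = small_dataset
        clf = self._tiny(labels, small_graphs, arch)
        g = small_graphs[5]
        perm = np.random.default_rng(7).permutation(g.n_nodes)
        p1 = clf.predict_proba([g])
        p2 = clf.predict_proba([_permute_graph(g, perm)])
        np.testing.assert_allclose(p1, p2, atol=1e-5)

    def test_scores_strictly_inside_unit_interval(self, small_dataset, small_graphs):
        _, labels = small_dataset
        clf = self._tiny(labels, small_graphs, "gcn")
        S = clf.predict_proba(small_graphs[:50])
        assert (S > 0).all() and (S < 1).all()

    def test_overfit_sanity_loss_decreases(self, small_dataset, small_graphs):
        _, labels = small_dataset
        clf = GNNClassifier(architecture="gcn", hidden_dim=32, n_layers=2,
                            dropout=0.0, max_epochs=60, patience=60, lr=5e-3, seed=0)
        clf.fit(small_graphs[:10], labels.values[:10],
                validation_data=(small_graphs[:10], labels.values[:10]))
        assert clf.history_[-1]["train_loss"] < clf.history_[0]["train_loss"]

    def test_seed_determinism(self, small_dataset, small_graphs):
        _, labels = small_dataset
        a = self._tiny(labels, small_graphs, "gcn", seed=3)
        b = self._tiny(labels, small_graphs, "gcn", seed=3)
        assert [h["val_macro_f1"] for h in a.history_] == [
            h["val_macro_f1"] for h in b.history_
        ]
        np.testing.assert_array_equal(
            a.predict_proba(small_graphs[:5]), b.predict_proba(small_graphs[:5])
        )

    def test_attention_accessor_shape(self, small_dataset, small_graphs):
        _, labels = small_dataset
        clf = self._tiny(labels, small_graphs, "gat")
        g = small_graphs[0]
        layers = clf.attention(g)
        assert len(layers) == clf.n_layers
        for layer in layers:
            assert layer["alpha"].shape == (g.n_edges + g.n_nodes, clf.gat_heads)

    def test_non_gat_attention_raises(self, small_dataset, small_graphs):
        _, labels = small_dataset
        clf = self._tiny(labels, small_graphs, "gcn")
        with pytest.raises(ValueError):
            clf.attention(small_graphs[0])

    def test_embedding_dimension_matches_hidden(self, trained_gcn, small_graphs):
        E = trained_gcn.embed(small_graphs[:7])
        assert E.shape == (7, trained_gcn.hidden_dim)

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            GNNClassifier().fit([], np.zeros((0, 2)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GNNConfig(hidden_dim=0)
        with pytest.raises(ValueError):
            GNNConfig(dropout=1.0)
        with pytest.raises(ValueError):
            GNNConfig(focal_alpha=0.0)

    def test_train_gnn_wrapper_returns_fitted_model(self, small_dataset, small_graphs):
        _, labels = small_dataset
        cfg = GNNConfig(architecture="gcn", hidden_dim=16, n_layers=1,
                        max_epochs=3, patience=3, seed=0)
        model = train_gnn(small_graphs[:30], labels.values[:30], cfg,
                          validation_data=(small_graphs[30:40], labels.values[30:40]))
        assert len(model.history_) >= 1
        assert model.predict_proba(small_graphs[:3]).shape == (3, labels.n_labels)
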