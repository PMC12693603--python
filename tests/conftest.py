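import numpy as np
import pytest

from odorpred.featurization import smiles_list_to_graphs
from odorpred.gnn import GNNClassifier
from odorpred.synthetic import GenerationConfig, generate_molecules, plant_labels


@pytest.fixture(scope="session")
def small_dataset():
    """300 grammar-generated molecules with planted labels."""
    cfg = GenerationConfig(n_molecules=300, seed=7)
    smiles = generate_molecules(cfg)
    labels = plant_labels(smiles, cfg)
    return smiles, labels


@pytest.fixture(scope="session")
def small_graphs(small_dataset):
    smiles, _ = small_dataset
    return smiles_list_to_graphs(smiles)


@pytest.fixture(scope="session")
def trained_gcn(small_dataset, small_graphs):
    """A small GCN fitted on the planted-rule molecules (shared, read-only)."""
    smiles, labels = small_dataset
    n = len(smiles)
    rng = np.random.default_rng(0)
    idx = rng.permutation(n)
    tr, va = idx[:220], idx[220:]
    clf = GNNClassifier(
        architecture="gcn", hidden_dim=32, n_layers=2, loss="focal",
        max_epochs=25, patience=10, seed=0,
    )
    clf.fit(
        [small_graphs[i] for i in tr], labels.values[tr],
        validation_data=([small_graphs[i] for i in va], labels.values[va]),
        label_names=labels.label_names,
    )
    return clf


@pytest.fixture(scope="session")
def trained_gat(small_dataset, small_graphs):
    """A small GAT (attention accessor needed by interpretability tests)."""
    smiles, labels = small_dataset
    n = len(smiles)
    rng = np.random.default_rng(1)
    idx = rng.permutation(n)
    tr, va = idx[:220], idx[220:]
    clf = GNNClassifier(
        architecture="gat", hidden_dim=32, n_layers=2, gat_heads=4, loss="focal",
        max_epochs=15, patience=8, seed=1,
    )
    clf.fit(
        [small_graphs[i] for i in tr], labels.values[tr],
        validation_data=([small_graphs[i] for i in va], labels.values[va]),
        label_names=labels.label_names,
    )
    return clf
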