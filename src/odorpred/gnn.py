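"""Graph neural networks for multi-label molecular property prediction.

Three message-passing architectures over molecular graphs, sharing a
global-mean-pooling readout and a two-layer sigmoid classification head:

* **GCN** — spectral graph convolution with symmetric normalization and
  self-loops: h'_i = σ(Σ_{j∈N(i)∪{i}} W h_j / √((d_i+1)(d_j+1))).
* **GAT** — multi-head additive attention over each neighborhood
  N(i)∪{i}; per-neighborhood softmax weights α_ij are retained for
  interpretability; heads are concatenated.
* **NNConv** — edge-conditioned convolution: a small edge network maps
  each 6-dimensional bond vector to a full linear transform Θ(e_ij), the
  message from j to i is Θ(e_ij)·h_j, aggregated by mean and combined
  with a root transform of h_i.

Three losses address label imbalance: plain binary cross-entropy,
inverse-frequency weighted BCE (positive-term weight w_k = (N−n_k)/n_k),
and focal loss L = −(1/N) Σ_i Σ_k α_k (1−p_ik)^γ log(p_ik) with p_ik the
confidence assigned to the true class.  Training uses Adam with
mini-batches, early stopping on validation macro F1 (thresholds fixed at
0.5 during training; calibration happens post hoc) and plateau learning-
rate decay.  Everything runs in float64 NumPy, so a fixed seed gives
bit-identical runs.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import Adam, Tensor, bmm, gather, segment_mean, segment_softmax, segment_sum
from .containers import as_label_array, as_score_array
from .evaluation import macro_f1_score
from .featurization import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, MolecularGraph

EPS = 1e-7


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """A disjoint union of molecular graphs."""

    x: np.ndarray           # (N, 25)
    edge_index: np.ndarray  # (2, E) without self-loops
    edge_attr: np.ndarray   # (E, 6)
    batch: np.ndarray       # (N,) graph id per node
    n_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        xs, eis, eas, batch = [], [], [], []
        offset = 0
        for g, graph in enumerate(graphs):
            xs.append(graph.node_features)
            eis.append(graph.edge_index + offset)
            eas.append(graph.edge_features)
            batch.append(np.full(graph.n_nodes, g, dtype=np.intp))
            offset += graph.n_nodes
        return cls(
            x=np.vstack(xs),
            edge_index=np.hstack(eis) if eis else np.zeros((2, 0), dtype=np.int64),
            edge_attr=np.vstack(eas) if eas else np.zeros((0, BOND_FEATURE_DIM)),
            batch=np.concatenate(batch),
            n_graphs=len(graphs),
        )

    def with_self_loops(self):
        n = self.x.shape[0]
        loops = np.arange(n, dtype=np.int64)
        src = np.concatenate([self.edge_index[0], loops])
        dst = np.concatenate([self.edge_index[1], loops])
        return src, dst


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-lim, lim, size=shape), requires_grad=True)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class GCNLayer:
    def __init__(self, rng, in_dim, out_dim):
        self.W = _glorot(rng, in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def params(self):
        return [self.W, self.b]

    def __call__(self, h: Tensor, batch: GraphBatch) -> Tensor:
        n = h.data.shape[0]
        src, dst = batch.with_self_loops()
        deg = np.bincount(batch.edge_index[1], minlength=n) + 1.0  # d_i + 1 (self-loop)
        coef = 1.0 / np.sqrt(deg[src] * deg[dst])
        hw = h @ self.W
        msg = gather(hw, src) * Tensor(coef[:, None])
        return segment_sum(msg, dst, n) + self.b


class GATLayer:
    def __init__(self, rng, in_dim, out_dim, heads):
        if out_dim % heads:
            raise ValueError("hidden_dim must be divisible by gat_heads")
        self.heads = heads
        self.head_dim = out_dim // heads
        self.W = _glorot(rng, in_dim, out_dim)
        self.a_src = _glorot(rng, self.head_dim, 1, shape=(heads, self.head_dim))
        self.a_dst = _glorot(rng, self.head_dim, 1, shape=(heads, self.head_dim))
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.alpha_: np.ndarray | None = None  # (E', H) attention of the last call
        self.edges_: tuple | None = None

    def params(self):
        return [self.W, self.a_src, self.a_dst, self.b]

    def __call__(self, h: Tensor, batch: GraphBatch) -> Tensor:
        n = h.data.shape[0]
        src, dst = batch.with_self_loops()
        hw = (h @ self.W).reshape(n, self.heads, self.head_dim)
        # additive attention logits per edge and head
        e_src = (hw * self.a_src.reshape(1, self.heads, self.head_dim)).sum(axis=2)
        e_dst = (hw * self.a_dst.reshape(1, self.heads, self.head_dim)).sum(axis=2)
        logits = (gather(e_src, src) + gather(e_dst, dst)).leaky_relu(0.2)
        alpha = segment_softmax(logits, dst, n)  # softmax over each dst neighborhood
        self.alpha_ = alpha.data.copy()
        self.edges_ = (src.copy(), dst.copy())
        msg = gather(hw, src) * alpha.reshape(alpha.data.shape[0], self.heads, 1)
        out = segment_sum(msg, dst, n).reshape(n, self.heads * self.head_dim)
        return out + self.b


class NNConvLayer:
    def __init__(self, rng, in_dim, out_dim, edge_dim=BOND_FEATURE_DIM, edge_hidden=16):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.W_root = _glorot(rng, in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.E1 = _glorot(rng, edge_dim, edge_hidden)
        self.e1 = Tensor(np.zeros(edge_hidden), requires_grad=True)
        self.E2 = _glorot(rng, edge_hidden, in_dim * out_dim)
        self.e2 = Tensor(np.zeros(in_dim * out_dim), requires_grad=True)

    def params(self):
        return [self.W_root, self.b, self.E1, self.e1, self.E2, self.e2]

    def __call__(self, h: Tensor, batch: GraphBatch) -> Tensor:
        if batch.edge_attr.shape[1] != BOND_FEATURE_DIM:
            raise ValueError("edge features are required for NNConv")
        n = h.data.shape[0]
        root = h @ self.W_root + self.b
        if batch.edge_index.shape[1] == 0:
            return root
        src, dst = batch.edge_index
        e = Tensor(batch.edge_attr)
        theta = ((e @ self.E1 + self.e1).relu() @ self.E2 + self.e2).reshape(
            -1, self.out_dim, self.in_dim
        )
        msg = bmm(theta, gather(h, src))
        return root + segment_mean(msg, dst, n)


class BatchNorm:
    def __init__(self, dim, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mean = x.mean(axis=0, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean.data[0]
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data[0]
        else:
            mean = Tensor(self.running_mean[None, :])
            var = Tensor(self.running_var[None, :])
        return (x - mean) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


# ---------------------------------------------------------------------------
# losses (NumPy-facing and Tensor-facing)
# ---------------------------------------------------------------------------

def focal_loss(scores, labels, alpha=0.25, gamma=2.0) -> float:
    """Focal loss on a probability matrix: mean over samples of the summed
    per-label terms α_k (1−p_ik)^γ (−log p_ik), with p_ik the confidence in
    the true class.  ``alpha`` may be a scalar or per-label vector."""
    p = np.clip(as_score_array(scores), EPS, 1 - EPS)
    y = as_label_array(labels)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (p.shape[1],))
    pt = np.where(y == 1, p, 1 - p)
    terms = alpha[None, :] * (1 - pt) ** gamma * (-np.log(pt))
    return float(terms.sum(axis=1).mean())


def bce_loss(scores, labels) -> float:
    """Plain BCE = focal loss at γ = 0, α = 1."""
    return focal_loss(scores, labels, alpha=1.0, gamma=0.0)


def weighted_bce_loss(scores, labels, pos_weight) -> float:
    p = np.clip(as_score_array(scores), EPS, 1 - EPS)
    y = as_label_array(labels)
    w = np.broadcast_to(np.asarray(pos_weight, dtype=float), (p.shape[1],))
    terms = -(w[None, :] * y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(terms.sum(axis=1).mean())


def _loss_t(p: Tensor, y: np.ndarray, kind: str, alpha, gamma, pos_weight) -> Tensor:
    """Tensor-valued training losses on clamped probabilities."""
    n, K = y.shape
    p = p.clip(EPS, 1 - EPS)
    yt = Tensor(y.astype(np.float64))
    if kind == "focal":
        a = Tensor(np.broadcast_to(np.asarray(alpha, dtype=float), (K,)).copy())
        pt = yt * p + (Tensor(np.ones_like(y, dtype=float)) - yt) * (1.0 - p)
        pt = pt.clip(EPS, 1 - EPS)
        terms = a * (1.0 - pt) ** gamma * (-pt.log())
    elif kind == "weighted_bce":
        w = Tensor(np.broadcast_to(np.asarray(pos_weight, dtype=float), (K,)).copy())
        terms = -(w * yt * p.log() + (1.0 - yt) * (1.0 - p).log())
    elif kind == "bce":
        terms = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log())
    else:
        raise ValueError(f"unknown loss {kind!r}")
    return terms.sum(axis=1).mean()


# ---------------------------------------------------------------------------
# configuration / model
# ---------------------------------------------------------------------------

@dataclass
class GNNConfig:
    """Everything that defines a GNN run."""

    architecture: str = "gcn"  # gcn | gat | nnconv
    hidden_dim: int = 64
    n_layers: int = 3
    gat_heads: int = 4
    dropout: float = 0.2
    batch_norm: bool = True
    loss: str = "focal"  # bce | weighted_bce | focal
    focal_alpha: float | list = 0.25
    focal_gamma: float = 2.0
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    lr_factor: float = 0.5
    lr_patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim < 1 or self.focal_gamma < 0:
            raise ValueError("hidden_dim ≥ 1 and focal_gamma ≥ 0 required")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        a = np.atleast_1d(np.asarray(self.focal_alpha, dtype=float))
        if (a <= 0).any() or (a > 1).any():
            raise ValueError("focal_alpha must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


class GNNClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style multi-label GNN classifier.

    ``fit(graphs, Y, validation_data=(val_graphs, val_Y))`` trains with
    mini-batch Adam, early stopping and plateau LR decay, restoring the
    best-validation checkpoint.  ``predict_proba`` returns (n, K) scores
    in (0, 1); ``embed`` returns the pooled graph vector before the head;
    ``attention`` (GAT only) returns the per-layer α_ij.
    """

    def __init__(self, architecture="gcn", hidden_dim=64, n_layers=3, gat_heads=4,
                 dropout=0.2, batch_norm=True, loss="focal", focal_alpha=0.25,
                 focal_gamma=2.0, lr=1e-3, batch_size=32, max_epochs=200,
                 patience=20, lr_factor=0.5, lr_patience=10, seed=0):
        self.architecture = architecture
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.gat_heads = gat_heads
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.loss = loss
        self.focal_alpha = focal_alpha
        self.focal_gamma = focal_gamma
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.lr_factor = lr_factor
        self.lr_patience = lr_patience
        self.seed = seed

    # -- construction ---------------------------------------------------
    def _build(self, n_labels: int, rng: np.random.Generator):
        self.convs_, self.bns_ = [], []
        in_dim = ATOM_FEATURE_DIM
        for _ in range(self.n_layers):
            if self.architecture == "gcn":
                self.convs_.append(GCNLayer(rng, in_dim, self.hidden_dim))
            elif self.architecture == "gat":
                self.convs_.append(GATLayer(rng, in_dim, self.hidden_dim, self.gat_heads))
            elif self.architecture == "nnconv":
                self.convs_.append(NNConvLayer(rng, in_dim, self.hidden_dim))
            else:
                raise ValueError(f"unknown architecture {self.architecture!r}")
            if self.batch_norm:
                self.bns_.append(BatchNorm(self.hidden_dim))
            in_dim = self.hidden_dim
        self.head_W1_ = _glorot(rng, self.hidden_dim, self.hidden_dim)
        self.head_b1_ = Tensor(np.zeros(self.hidden_dim), requires_grad=True)
        self.head_W2_ = _glorot(rng, self.hidden_dim, n_labels)
        self.head_b2_ = Tensor(np.zeros(n_labels), requires_grad=True)

    def _params(self):
        ps = []
        for c in self.convs_:
            ps += c.params()
        for b in self.bns_:
            ps += b.params()
        ps += [self.head_W1_, self.head_b1_, self.head_W2_, self.head_b2_]
        return ps

    # -- forward --------------------------------------------------------
    def _forward(self, batch: GraphBatch, training: bool, rng=None, x: Tensor | None = None):
        h = Tensor(batch.x) if x is None else x
        for i, conv in enumerate(self.convs_):
            h = conv(h, batch)
            if self.batch_norm:
                h = self.bns_[i](h, training)
            h = h.relu()
            if training and self.dropout > 0:
                mask = (rng.random(h.data.shape) >= self.dropout) / (1 - self.dropout)
                h = h * Tensor(mask)
        pooled = segment_mean(h, batch.batch, batch.n_graphs)
        z = (pooled @ self.head_W1_ + self.head_b1_).relu()
        if training and self.dropout > 0:
            mask = (rng.random(z.data.shape) >= self.dropout) / (1 - self.dropout)
            z = z * Tensor(mask)
        logits = z @ self.head_W2_ + self.head_b2_
        return logits, pooled

    # -- training -------------------------------------------------------
    def fit(self, graphs: list[MolecularGraph], Y, validation_data=None, label_names=None):
        Yv = as_label_array(Y)
        if len(graphs) != Yv.shape[0]:
            raise ValueError("graphs and labels must be aligned")
        if len(graphs) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 10]))
        if validation_data is None:
            idx = rng.permutation(len(graphs))
            n_val = max(1, int(0.15 * len(graphs)))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            val_graphs = [graphs[i] for i in val_idx]
            val_Y = Yv[val_idx]
            graphs = [graphs[i] for i in tr_idx]
            Yv = Yv[tr_idx]
        else:
            val_graphs, val_Y = validation_data
            val_Y = as_label_array(val_Y)
        if len(val_graphs) == 0:
            raise ValueError("empty validation set")

        K = Yv.shape[1]
        self.label_names_ = list(label_names) if label_names is not None else (
            getattr(Y, "label_names", None) or [f"label_{k}" for k in range(K)]
        )
        self._build(K, rng)
        n_pos = Yv.sum(axis=0).astype(float)
        self.pos_weight_ = np.where(n_pos > 0, (len(graphs) - n_pos) / np.maximum(n_pos, 1), 1.0)

        opt = Adam(self._params(), lr=self.lr)
        best_f1, best_state, best_epoch = -np.inf, None, 0
        lr_wait = 0
        self.history_ = []
        n = len(graphs)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                bidx = order[start : start + self.batch_size]
                batch = GraphBatch.from_graphs([graphs[i] for i in bidx])
                logits, _ = self._forward(batch, training=True, rng=rng)
                p = logits.sigmoid()
                loss = _loss_t(p, Yv[bidx], self.loss, self.focal_alpha,
                               self.focal_gamma, self.pos_weight_)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            val_scores = self.predict_proba(val_graphs)
            val_f1 = macro_f1_score(val_Y, (val_scores >= 0.5).astype(int))
            self.history_.append(
                {"epoch": epoch, "train_loss": float(np.mean(losses)),
                 "val_macro_f1": val_f1, "lr": opt.lr}
            )
            if val_f1 > best_f1 + 1e-12:
                best_f1, best_epoch = val_f1, epoch
                best_state = [p.data.copy() for p in self._params()]
                best_bn = [(b.running_mean.copy(), b.running_var.copy()) for b in self.bns_]
                lr_wait = 0
            else:
                lr_wait += 1
                if lr_wait >= self.lr_patience:
                    opt.lr *= self.lr_factor
                    lr_wait = 0
            if epoch - best_epoch >= self.patience:
                break
        if best_state is not None:
            for p, d in zip(self._params(), best_state):
                p.data = d
            for b, (m, v) in zip(self.bns_, best_bn):
                b.running_mean, b.running_var = m, v
        self.best_val_f1_ = float(best_f1)
        return self

    # -- inference ------------------------------------------------------
    def predict_proba(self, graphs) -> np.ndarray:
        batch = GraphBatch.from_graphs(list(graphs))
        logits, _ = self._forward(batch, training=False)
        return 1.0 / (1.0 + np.exp(-logits.data))

    def decision_function(self, graphs) -> np.ndarray:
        batch = GraphBatch.from_graphs(list(graphs))
        logits, _ = self._forward(batch, training=False)
        return logits.data

    def predict(self, graphs, thresholds=None) -> np.ndarray:
        S = self.predict_proba(graphs)
        t = np.full(S.shape[1], 0.5) if thresholds is None else np.asarray(thresholds, float)
        return (S >= t[None, :]).astype(np.int64)

    def embed(self, graphs) -> np.ndarray:
        """Pooled graph-level embeddings (input of the classification head)."""
        batch = GraphBatch.from_graphs(list(graphs))
        _, pooled = self._forward(batch, training=False)
        return pooled.data

    def attention(self, graph: MolecularGraph) -> list[dict]:
        """Per-layer attention of a single molecule (GAT only).

        Returns one dict per layer: {'src', 'dst', 'alpha' (E', H)} where
        the edge list includes self-loops."""
        if self.architecture != "gat":
            raise ValueError("attention weights exist only for GAT models")
        batch = GraphBatch.from_graphs([graph])
        self._forward(batch, training=False)
        return [
            {"src": c.edges_[0], "dst": c.edges_[1], "alpha": c.alpha_}
            for c in self.convs_
        ]

    def input_gradient(self, graph: MolecularGraph, label_index: int) -> np.ndarray:
        """∂(pre-sigmoid logit of one label)/∂(node features), shape (n, 25)."""
        K = self.head_b2_.data.shape[0]
        if not (0 <= label_index < K):
            raise IndexError(f"label index {label_index} out of range (K={K})")
        batch = GraphBatch.from_graphs([graph])
        x = Tensor(batch.x, requires_grad=True)
        logits, _ = self._forward(batch, training=False, x=x)
        seed_grad = np.zeros_like(logits.data)
        seed_grad[0, label_index] = 1.0
        logits.backward(seed_grad)
        return x.grad.copy()


def train_gnn(graphs, labels, config: GNNConfig, validation_data=None, label_names=None) -> GNNClassifier:
    """Train a GNN per the given configuration and return the fitted model."""
    clf = GNNClassifier(**config.to_dict())
    return clf.fit(graphs, labels, validation_data=validation_data, label_names=label_names)


# ---------------------------------------------------------------------------
# functional single-layer forms (handy for direct numerical checks)
# ---------------------------------------------------------------------------

def gcn_layer(node_features, edge_index, weights, bias=None):
    """One GCN propagation h' = Σ c_ij W h_j (linear activation)."""
    x = np.asarray(node_features, dtype=float)
    ei = np.asarray(edge_index, dtype=np.int64).reshape(2, -1)
    n = x.shape[0]
    layer = GCNLayer(np.random.default_rng(0), x.shape[1], np.asarray(weights).shape[1])
    layer.W = Tensor(np.asarray(weights, dtype=float))
    layer.b = Tensor(np.zeros(np.asarray(weights).shape[1]) if bias is None else np.asarray(bias, float))
    batch = GraphBatch(x, ei, np.zeros((ei.shape[1], BOND_FEATURE_DIM)), np.zeros(n, dtype=np.intp), 1)
    return layer(Tensor(x), batch).data


def gat_layer(node_features, edge_index, layer: GATLayer):
    """One GAT propagation; returns (h', attention dict)."""
    x = np.asarray(node_features, dtype=float)
    ei = np.asarray(edge_index, dtype=np.int64).reshape(2, -1)
    n = x.shape[0]
    batch = GraphBatch(x, ei, np.zeros((ei.shape[1], BOND_FEATURE_DIM)), np.zeros(n, dtype=np.intp), 1)
    out = layer(Tensor(x), batch).data
    return out, {"src": layer.edges_[0], "dst": layer.edges_[1], "alpha": layer.alpha_}


def nnconv_layer(node_features, edge_index, edge_features, layer: NNConvLayer):
    """One edge-conditioned propagation."""
    x = np.asarray(node_features, dtype=float)
    ei = np.asarray(edge_index, dtype=np.int64).reshape(2, -1)
    ef = np.asarray(edge_features, dtype=float)
    if ef.ndim != 2 or ef.shape[0] != ei.shape[1]:
        raise ValueError("edge features missing or misaligned")
    batch = GraphBatch(x, ei, ef, np.zeros(x.shape[0], dtype=np.intp), 1)
    return layer(Tensor(x), batch).data
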