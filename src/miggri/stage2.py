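"""Stage 2: two-layer GraphSAGE-mean link prediction over the known graph.

Each layer averages neighbor states, concatenates with the node's own state
and applies a learned linear map plus nonlinearity:

    h_N(i) = mean{ h_j : j in N(i) }          (zero vector if N(i) empty)
    h_i'   = sigma( W . concat(h_i, h_N(i)) )

The decision head is the sigmoid of the dot product of the two final node
embeddings, so predictions are symmetric in (i, j).  Training minimizes
binary cross-entropy over the labeled train links; only train-positive
edges enter the message-passing adjacency (val/test edges never do — a
leakage guard asserts this on every run).  The recurrent aggregator, when
chosen, is trained jointly: each epoch the image-embedding order is
re-shuffled and node features are recomputed through the LSTM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .aggregate import AggregatorSpec, LSTMAggregator, epoch_shuffle, make_aggregator
from .data import GRNGraph, SplitSpec
from .metrics import compute_metrics

__all__ = [
    "GNNConfig",
    "GraphSAGE",
    "Stage2Model",
    "sage_layer",
    "predict_link",
    "train_stage2",
    "neighbor_mean_matrix",
    "embeddings_by_gene",
    "build_node_features",
]


@dataclass
class GNNConfig:
    hidden_dims: tuple[int, int] = (64, 32)
    activation: str = "relu"  # relu | elu (between layers; head is sigmoid)
    learning_rate: float = 5e-4
    epochs: int = 150
    decision_threshold: float = 0.5
    seed: int = 0
    feature_mode: str = "image"  # image | random_init (topology-only baseline)
    trainable_features: bool = False  # tune node features by gradient during training
    normalize_features: bool = True  # L2-normalize static node feature rows
    init: str = "signal_preserving"  # or "random"
    checkpoint: str = "best"  # best (validation AUC) | final
    backbone: str = "graphsage_mean"  # recorded for forward compatibility
    n_layers: int = 2

    def __post_init__(self):
        if self.n_layers != 2:
            raise ValueError("the architecture is fixed at two layers")
        if len(self.hidden_dims) != 2:
            raise ValueError("hidden_dims must have two entries")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")
        if self.activation not in ("relu", "elu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.feature_mode not in ("image", "random_init"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.backbone != "graphsage_mean":
            raise ValueError("only the graphsage_mean backbone is implemented")

    @classmethod
    def preset(cls, name: str, **overrides) -> "GNNConfig":
        """Named presets: reference settings for the two real networks and
        the desk-scale synthetic benchmark."""
        presets = {
            "eye": dict(learning_rate=5e-2, epochs=78, init="random"),
            "mesoderm": dict(learning_rate=5e-2, epochs=3, init="random"),
            "benchmark": dict(learning_rate=5e-4, epochs=150),
        }
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}")
        return cls(**{**presets[name], **overrides})


# ---------------------------------------------------------------------------
# reference ops (plain numpy; autodiff path mirrors them)


def _activate(x: np.ndarray, activation) -> np.ndarray:
    if callable(activation):
        return activation(x)
    if activation == "relu":
        return np.maximum(x, 0.0)
    if activation == "elu":
        return np.where(x > 0, x, np.expm1(x))
    if activation in (None, "identity"):
        return x
    raise ValueError(f"unknown activation {activation!r}")


def sage_layer(H, A, W, activation="relu", bias=None) -> np.ndarray:
    """One GraphSAGE-mean layer on plain arrays.

    H: (n, d) node states; A: (n, n) symmetric binary adjacency;
    W: (d_out, 2d) weight applied to concat(h_i, h_N(i)); isolated nodes use
    the zero vector as their neighborhood mean.
    """
    H = np.asarray(H, dtype=float)
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    n, d = H.shape
    if A.shape != (n, n):
        raise ValueError(f"adjacency shape {A.shape} does not match {n} nodes")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if W.shape[1] != 2 * d:
        raise ValueError(f"weight expects concat dim {W.shape[1]}, got {2 * d}")
    deg = A.sum(axis=1)
    h_neigh = (A @ H) / np.where(deg > 0, deg, 1.0)[:, None]
    z = np.concatenate([H, h_neigh], axis=1) @ W.T
    if bias is not None:
        z = z + bias
    return _activate(z, activation)


def predict_link(h_i: np.ndarray, h_j: np.ndarray) -> float:
    """Decision head: sigmoid of the dot product of two final embeddings."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    if h_i.shape != h_j.shape:
        raise ValueError("embedding dimension mismatch")
    z = float(h_i @ h_j)
    return float(1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))))


def neighbor_mean_matrix(A: np.ndarray) -> np.ndarray:
    """Row-normalized adjacency: P @ H gives per-node neighborhood means."""
    A = np.asarray(A, dtype=float)
    deg = A.sum(axis=1)
    return A / np.where(deg > 0, deg, 1.0)[:, None]


# ---------------------------------------------------------------------------
# model


class GraphSAGE(nn.Module):
    """Two GraphSAGE-mean layers with biases, as an autodiff module.

    With ``init='signal_preserving'`` (and shapes h1 >= 2*d, h2 >= d) the
    weights start as a ReLU-pair identity map on the node's own features
    (relu(x) - relu(-x) = x reassembled in layer two), with small random
    weights elsewhere: at epoch 0 the model scores links by the dot product
    of the raw node features, and training grows the topology terms on top
    instead of first scrambling the feature signal.
    """

    def __init__(self, in_dim: int, hidden_dims: tuple[int, int], rng,
                 activation="relu", init: str = "signal_preserving"):
        h1, h2 = hidden_dims
        self.lin1 = nn.Linear(2 * in_dim, h1, rng)
        self.lin2 = nn.Linear(2 * h1, h2, rng)
        self.activation = activation
        if init == "signal_preserving" and h1 >= 2 * in_dim and h2 >= in_dim:
            d = in_dim
            w1 = 0.01 * rng.normal(size=(2 * in_dim, h1))
            w1[:d, :d] += np.eye(d)
            w1[:d, d : 2 * d] -= np.eye(d)
            self.lin1.w.data = w1
            w2 = 0.01 * rng.normal(size=(2 * h1, h2))
            w2[:d, :d] += np.eye(d)
            w2[d : 2 * d, :d] -= np.eye(d)
            self.lin2.w.data = w2
        elif init not in ("signal_preserving", "random"):
            raise ValueError(f"unknown init {init!r}")

    def _act(self, x: nn.Tensor) -> nn.Tensor:
        if self.activation == "relu":
            return x.relu()
        # elu via composition: x>0 ? x : exp(x)-1
        pos = x.relu()
        neg = (-((-x).relu())).exp() - 1.0
        return pos + neg * ((x.numpy() <= 0).astype(float))

    def forward(self, X: nn.Tensor, P: nn.Tensor) -> nn.Tensor:
        """X: (n, d) node features; P: (n, n) neighbor-averaging operator."""
        h1 = self._act(nn.concat([X, P @ X], axis=1) @ self.lin1.w + self.lin1.b)
        h2 = nn.concat([h1, P @ h1], axis=1) @ self.lin2.w + self.lin2.b
        return h2  # no activation before the dot-product head


class Stage2Model:
    """Trained link predictor: graph + node features + GraphSAGE weights."""

    def __init__(
        self,
        graph: GRNGraph,
        adjacency: np.ndarray,
        features: np.ndarray,
        gnn: GraphSAGE,
        cfg: GNNConfig,
        aggregator=None,
    ):
        self.graph = graph
        self.adjacency = adjacency  # message-passing adjacency (train-pos only)
        self.features = features  # H^(0) rows, graph.nodes order
        self.gnn = gnn
        self.cfg = cfg
        self.aggregator = aggregator

    def node_embeddings(
        self, features: np.ndarray | None = None, adjacency: np.ndarray | None = None
    ) -> np.ndarray:
        X = self.features if features is None else features
        A = self.adjacency if adjacency is None else adjacency
        with nn.no_grad():
            return self.gnn.forward(
                nn.Tensor(X), nn.Tensor(neighbor_mean_matrix(A))
            ).numpy()

    def predict_pairs(self, pairs, features=None, adjacency=None) -> np.ndarray:
        H = self.node_embeddings(features, adjacency)
        idx = self.graph.index
        return np.array([predict_link(H[idx[a]], H[idx[b]]) for a, b in pairs])

    def state_dict(self):
        state = {f"gnn.{k}": v for k, v in self.gnn.state_dict().items()}
        if isinstance(self.aggregator, LSTMAggregator):
            state.update({f"agg.{k}": v for k, v in self.aggregator.state_dict().items()})
        return state


def _assert_no_leak(adjacency: np.ndarray, graph: GRNGraph, split: SplitSpec) -> None:
    for name, pairs in (("val", split.val_pos), ("test", split.test_pos)):
        for a, b in pairs:
            if adjacency[graph.index[a], graph.index[b]]:
                raise AssertionError(
                    f"leakage: {name} edge ({a}, {b}) present in the "
                    "message-passing adjacency"
                )


def adjacency_from_edges(graph: GRNGraph, edges) -> np.ndarray:
    A = np.zeros((graph.n_nodes, graph.n_nodes))
    for a, b in edges:
        i, j = graph.index[a], graph.index[b]
        A[i, j] = A[j, i] = 1.0
    return A


# ---------------------------------------------------------------------------
# node features


def embeddings_by_gene(image_embeddings: pd.DataFrame) -> dict[str, np.ndarray]:
    """Split a stage-1 embedding table into per-gene (k, d) arrays."""
    vcols = [c for c in image_embeddings.columns if c.startswith("v")]
    out = {}
    for gene, sub in image_embeddings.groupby("gene_id", sort=True):
        out[str(gene)] = sub.sort_values(["orientation", "image_index"])[vcols].to_numpy()
    return out


def build_node_features(
    graph: GRNGraph,
    per_gene: dict[str, np.ndarray],
    aggregator,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Aggregate per-image embeddings into the H^(0) feature matrix.

    Genes with no images get a random-normal feature on the scale of the
    observed aggregated features (per-dimension sd); the list of such genes
    is returned alongside.
    """
    aggregated = {g: aggregator(v) for g, v in per_gene.items() if len(v)}
    if not aggregated:
        raise ValueError("no gene has any image embedding")
    d = len(next(iter(aggregated.values())))
    obs = np.stack(list(aggregated.values()))
    scale = obs.std(axis=0)
    featureless = [g for g in graph.nodes if g not in aggregated]
    X = np.zeros((graph.n_nodes, d))
    for g in graph.nodes:
        i = graph.index[g]
        X[i] = aggregated[g] if g in aggregated else rng.normal(0.0, scale)
    return X, featureless


# ---------------------------------------------------------------------------
# training


def _bce(scores: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    y = np.asarray(labels, dtype=float)
    eps = 1e-12
    return -(
        (scores + eps).log() * y + (1.0 - scores + eps).log() * (1.0 - y)
    ).mean()


def _pair_scores(H: nn.Tensor, idx_a, idx_b) -> nn.Tensor:
    return (H.gather_rows(idx_a) * H.gather_rows(idx_b)).sum(axis=1).sigmoid()


def train_stage2(
    graph: GRNGraph,
    split: SplitSpec,
    cfg: GNNConfig,
    image_embeddings: pd.DataFrame | None = None,
    features: np.ndarray | None = None,
    agg_spec: AggregatorSpec | None = None,
    random_dim: int = 32,
    tune_feature_genes=None,
) -> tuple[Stage2Model, pd.DataFrame, dict]:
    """Train the link predictor; returns (model, test predictions, history).

    Node features come from one of three sources: a precomputed ``features``
    matrix, a stage-1 ``image_embeddings`` table aggregated by ``agg_spec``
    (the LSTM aggregator trains jointly with the GNN), or — with
    ``cfg.feature_mode='random_init'`` — fixed random normal vectors (the
    topology-only baseline).  ``tune_feature_genes`` names genes whose
    feature rows are trained by gradient even when features are otherwise
    static — the missing-data protocol tunes exactly the randomly
    initialized featureless genes this way.
    """
    rng = np.random.default_rng(cfg.seed)
    adjacency = adjacency_from_edges(graph, split.train_pos)
    _assert_no_leak(adjacency, graph, split)
    P = nn.Tensor(neighbor_mean_matrix(adjacency))

    agg_spec = agg_spec or AggregatorSpec(kind="mean")
    aggregator = None
    per_gene = None
    joint_lstm = False
    X_param: nn.Tensor | None = None
    if cfg.feature_mode == "random_init":
        # topology-only baseline: random node features, no image information
        X_static = rng.standard_normal((graph.n_nodes, random_dim))
    elif features is not None:
        X_static = np.asarray(features, dtype=float).copy()
    elif image_embeddings is not None:
        per_gene = embeddings_by_gene(image_embeddings)
        input_dim = next(iter(per_gene.values())).shape[1]
        aggregator = make_aggregator(agg_spec, input_dim)
        joint_lstm = isinstance(aggregator, LSTMAggregator)
        if not joint_lstm:
            X_static, _ = build_node_features(graph, per_gene, aggregator, rng)
    else:
        raise ValueError("provide features, image_embeddings, or feature_mode='random_init'")
    if not joint_lstm and cfg.normalize_features:
        # unit-norm rows put the dot-product head on cosine geometry
        X_static = X_static / (np.linalg.norm(X_static, axis=1, keepdims=True) + 1e-12)
    tune_mask = None
    if not joint_lstm and cfg.trainable_features:
        # node features as parameters: initialized from the aggregated image
        # embeddings (or random vectors) and updated during training
        X_param = nn.Tensor(X_static, requires_grad=True)
    elif not joint_lstm and tune_feature_genes:
        X_param = nn.Tensor(X_static, requires_grad=True)
        tune_mask = np.zeros(graph.n_nodes, dtype=bool)
        for g in tune_feature_genes:
            tune_mask[graph.index[g]] = True

    if joint_lstm:
        in_dim = aggregator.hidden_dim
    else:
        in_dim = X_static.shape[1]
    gnn = GraphSAGE(in_dim, cfg.hidden_dims, np.random.default_rng(cfg.seed + 1),
                    activation=cfg.activation, init=cfg.init)

    idx = graph.index
    def pair_idx(pairs):
        return (np.array([idx[a] for a, _ in pairs]), np.array([idx[b] for _, b in pairs]))

    train_pairs = list(split.train_pos) + list(split.train_neg)
    train_labels = np.array([1] * len(split.train_pos) + [0] * len(split.train_neg))
    tr_a, tr_b = pair_idx(train_pairs)
    val_pairs = list(split.val_pos) + list(split.val_neg)
    val_labels = [1] * len(split.val_pos) + [0] * len(split.val_neg)
    va, vb = pair_idx(val_pairs) if val_pairs else (None, None)

    params = gnn.parameters() + (aggregator.parameters() if joint_lstm else [])
    if X_param is not None:
        params = params + [X_param]
    opt = nn.Adam(params, lr=cfg.learning_rate)

    def node_feature_tensor(epoch: int) -> nn.Tensor:
        if X_param is not None:
            return X_param
        if not joint_lstm:
            return nn.Tensor(X_static)
        seqs = {g: [per_gene[g][k] for k in range(len(per_gene[g]))]
                for g in per_gene if len(per_gene[g])}
        if agg_spec.shuffle_each_epoch:
            seqs = epoch_shuffle(seqs, epoch, agg_spec.seed)
        rows: list = [None] * graph.n_nodes
        missing_rng = np.random.default_rng(cfg.seed + 7)
        for g in graph.nodes:
            if g in seqs:
                rows[idx[g]] = aggregator.forward(nn.Tensor(np.stack(seqs[g])))
            else:
                rows[idx[g]] = nn.Tensor(
                    missing_rng.normal(0.0, 1.0, size=aggregator.hidden_dim)
                )
        return nn.stack(rows, axis=0)

    history = {"train_loss": [], "val_auc": [], "best_epoch": None}
    best = (-np.inf, None, None)  # (val auc, state, features snapshot)
    for epoch in range(cfg.epochs):
        X_t = node_feature_tensor(epoch)
        H = gnn.forward(X_t, P)
        scores = _pair_scores(H, tr_a, tr_b)
        loss = _bce(scores, train_labels)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"non-finite stage-2 loss at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        if tune_mask is not None and X_param.grad is not None:
            X_param.grad[~tune_mask] = 0.0
        opt.step()
        history["train_loss"].append(loss.item())

        if val_pairs:
            with nn.no_grad():
                Xv = node_feature_tensor(epoch)
                Hv = gnn.forward(Xv, P).numpy()
            v_scores = [predict_link(Hv[i], Hv[j]) for i, j in zip(va, vb)]
            auc = compute_metrics(zip(val_labels, v_scores)).auc
            history["val_auc"].append(auc)
            if auc > best[0]:
                state = {k: v.data.copy() for k, v in zip(
                    ("p%d" % i for i in range(len(params))), params)}
                best = (auc, state, Xv.numpy().copy())
                history["best_epoch"] = epoch

    # final features (post-training LSTM pass or static matrix)
    with nn.no_grad():
        X_final = node_feature_tensor(cfg.epochs)
    X_out = X_final.numpy()
    if cfg.checkpoint == "best" and best[1] is not None:
        for key, p in zip(("p%d" % i for i in range(len(params))), params):
            p.data = best[1][key].copy()
        X_out = best[2]

    model = Stage2Model(graph, adjacency, X_out, gnn, cfg, aggregator)
    test_pairs = list(split.test_pos) + list(split.test_neg)
    test_labels = [1] * len(split.test_pos) + [0] * len(split.test_neg)
    test_scores = model.predict_pairs(test_pairs)
    preds = pd.DataFrame({
        "gene_a": [a for a, _ in test_pairs],
        "gene_b": [b for _, b in test_pairs],
        "label": test_labels,
        "score": test_scores,
        "call": (test_scores >= cfg.decision_threshold).astype(int),
    })
    return model, preds, history


def save_model(model: Stage2Model, path) -> None:
    path = Path(path)
    np.savez(path, features=model.features, adjacency=model.adjacency,
             **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(asdict(model.cfg), indent=1))
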