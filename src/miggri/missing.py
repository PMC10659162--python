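"""Missing-feature protocol: evaluation tasks and gradient feature inference.

A fraction of genes is declared featureless (their aggregated image features
are hidden, never destroyed) and replaced by random normal vectors on the
scale of the observed features.  Three evaluation tasks probe robustness:

* Task I   — train and test only on links between featured genes
             (the featureless genes and their links are dropped).
* Task II  — train on all links (featured + featureless genes), test on
             links between featured genes.
* Task III — train as in Task II, test on links touching featureless genes.

Tasks share per-repeat splits so Task I vs II differences can be assessed
with a paired t-test.  Separately, :func:`infer_features` recovers feature
vectors for genes added to a frozen trained model by gradient descent on
the training-link cross-entropy restricted to their incident links — the
mechanism used both for Task-III-style prediction and for decoding unseen
genes' expression images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .data import GRNGraph, SplitSpec, make_splits
from .metrics import compute_metrics
from .stage2 import (
    GNNConfig,
    Stage2Model,
    adjacency_from_edges,
    neighbor_mean_matrix,
    predict_link,
    train_stage2,
)

__all__ = [
    "MissingDataTaskSpec",
    "InferredFeature",
    "run_missing_task",
    "run_missing_tasks",
    "infer_features",
    "paired_t_test",
]


@dataclass
class MissingDataTaskSpec:
    task: str  # "I" | "II" | "III"
    missing_frac: float = 0.10
    init_scale: float | None = None  # None: per-dimension sd of observed features
    n_repeats: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("I", "II", "III"):
            raise ValueError("task must be 'I', 'II' or 'III'")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must be in [0, 1)")


@dataclass
class InferredFeature:
    gene_id: str
    vector: np.ndarray
    n_steps: int
    final_loss: float
    init_loss: float


def paired_t_test(diffs) -> tuple[float, float]:
    """Two-sided paired t-test from the textbook formula on the differences."""
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least two paired differences")
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, 1.0) if d.mean() == 0 else (np.inf * np.sign(d.mean()), 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def _restrict_pairs(pairs, keep: set) -> list:
    return [(a, b) for a, b in pairs if a in keep and b in keep]


def _touching_pairs(pairs, group: set) -> list:
    return [(a, b) for a, b in pairs if a in group or b in group]


def _subsplit(split: SplitSpec, keep: set) -> SplitSpec:
    return SplitSpec(
        train_pos=_restrict_pairs(split.train_pos, keep),
        val_pos=_restrict_pairs(split.val_pos, keep),
        test_pos=_restrict_pairs(split.test_pos, keep),
        train_neg=_restrict_pairs(split.train_neg, keep),
        val_neg=_restrict_pairs(split.val_neg, keep),
        test_neg=_restrict_pairs(split.test_neg, keep),
        seed=split.seed,
    )


def _score_pairs(model: Stage2Model, pos, neg, threshold: float):
    pairs = list(pos) + list(neg)
    labels = [1] * len(pos) + [0] * len(neg)
    scores = model.predict_pairs(pairs)
    return compute_metrics(zip(labels, scores), threshold=threshold)


def run_missing_tasks(
    graph: GRNGraph,
    features: np.ndarray,
    cfg: GNNConfig,
    missing_frac: float = 0.10,
    n_repeats: int = 20,
    seed: int = 0,
    init_scale: float | None = None,
) -> pd.DataFrame:
    """Run Tasks I-III on shared per-repeat splits; one metrics row per
    (repeat, task).

    ``features`` holds the aggregated image feature of every gene (row order
    = graph.nodes); the protocol hides — never mutates — the rows of the
    genes drawn as featureless in each repeat.
    """
    n = graph.n_nodes
    rows = []
    for rep in range(n_repeats):
        rep_rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        rep_seed = int(rep_rng.integers(0, 2**31 - 1))
        n_missing = int(round(missing_frac * n))
        if missing_frac > 0 and (n_missing == 0 or n_missing >= n):
            raise ValueError("missing_frac leaves an empty partition")
        missing = set(
            np.asarray(graph.nodes)[rep_rng.permutation(n)[:n_missing]].tolist()
        ) if n_missing else set()
        featured = set(graph.nodes) - missing
        split = make_splits(graph, seed=rep_seed)
        run_cfg = GNNConfig(**{**vars(cfg), "seed": rep_seed})

        # Task I: featureless genes and their links removed entirely
        graph_i = GRNGraph(
            sorted(featured), _restrict_pairs(graph.edges, featured)
        )
        feats_i = features[[graph.index[g] for g in graph_i.nodes]]
        model_i, _, _ = train_stage2(graph_i, _subsplit(split, featured), run_cfg,
                                     features=feats_i)
        m1 = _score_pairs(model_i, _restrict_pairs(split.test_pos, featured),
                          _restrict_pairs(split.test_neg, featured),
                          run_cfg.decision_threshold)
        rows.append({"repeat": rep, "task": "I", **m1.as_dict()})

        # Task II/III: full graph, featureless rows replaced by random init
        X = features.copy()
        if missing:
            scale = (
                init_scale
                if init_scale is not None
                else features[[graph.index[g] for g in sorted(featured)]].std(axis=0)
            )
            for g in sorted(missing):
                X[graph.index[g]] = rep_rng.normal(0.0, scale)
        model_ii, _, _ = train_stage2(
            graph, split, run_cfg, features=X,
            tune_feature_genes=sorted(missing),
        )
        m2 = _score_pairs(model_ii, _restrict_pairs(split.test_pos, featured),
                          _restrict_pairs(split.test_neg, featured),
                          run_cfg.decision_threshold)
        rows.append({"repeat": rep, "task": "II", **m2.as_dict()})

        if missing:
            pos3 = _touching_pairs(split.test_pos, missing)
            neg3 = _touching_pairs(split.test_neg, missing)
            if pos3 and neg3:
                m3 = _score_pairs(model_ii, pos3, neg3, run_cfg.decision_threshold)
                rows.append({"repeat": rep, "task": "III", **m3.as_dict()})
    return pd.DataFrame(rows)


def run_missing_task(
    spec: MissingDataTaskSpec, graph: GRNGraph, features: np.ndarray, cfg: GNNConfig
) -> pd.DataFrame:
    """Per-repeat metrics for one task (convenience wrapper over the shared run)."""
    df = run_missing_tasks(
        graph, features, cfg,
        missing_frac=spec.missing_frac, n_repeats=spec.n_repeats,
        seed=spec.seed, init_scale=spec.init_scale,
    )
    return df[df["task"] == spec.task].reset_index(drop=True)


def summarize_tasks(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of each metric per task, plus the paired I-vs-II t-test."""
    summary = df.groupby("task")[["accuracy", "f1", "auc"]].agg(["mean", "std"])
    return summary


# ---------------------------------------------------------------------------
# gradient feature inference for genes added to a frozen model


def infer_features(
    model: Stage2Model,
    graph_full: GRNGraph,
    train_pos,
    train_neg,
    new_gene_ids,
    steps: int = 300,
    lr: float = 0.5,
    seed: int = 0,
    init_scale: float | None = None,
    exclude_new_links_from_adjacency: bool = True,
    project_unit_norm: bool = True,
) -> list[InferredFeature]:
    """Infer feature vectors for newly attached genes by gradient descent.

    The model's weights and the old genes' features stay untouched; only the
    new rows (initialized random-normal on the observed feature scale) are
    optimized, against the binary cross-entropy of the training links
    incident to new genes.  By default those supervision links are excluded
    from the message-passing adjacency (a link used as a label is never also
    a message path — otherwise the gradient can inflate the new feature's
    norm through its partner's neighborhood instead of aligning its
    direction), and the optimized rows are projected back to unit norm each
    step, keeping them on the scale of the trained features.  The step size
    is halved whenever the loss increases, at most three times; new genes
    with no incident training links are returned at their initialization
    with a warning.
    """
    rng = np.random.default_rng(seed)
    new_ids = list(new_gene_ids)
    new_set = set(new_ids)
    d = model.features.shape[1]
    scale = init_scale if init_scale is not None else model.features.std(axis=0)

    X = np.zeros((graph_full.n_nodes, d))
    for g in graph_full.nodes:
        if g in new_set:
            v = rng.normal(0.0, scale)
            if project_unit_norm:
                v = v / (np.linalg.norm(v) + 1e-12)
            X[graph_full.index[g]] = v
        else:
            X[graph_full.index[g]] = model.features[model.graph.index[g]]
    init_X = X.copy()

    mp_edges = (
        [(a, b) for a, b in train_pos if a not in new_set and b not in new_set]
        if exclude_new_links_from_adjacency
        else list(train_pos)
    )
    adjacency = adjacency_from_edges(graph_full, mp_edges)
    P = nn.Tensor(neighbor_mean_matrix(adjacency))
    inc_pos = _touching_pairs(train_pos, new_set)
    inc_neg = _touching_pairs(train_neg, new_set)
    pairs = inc_pos + inc_neg
    labels = np.array([1.0] * len(inc_pos) + [0.0] * len(inc_neg))
    idx = graph_full.index
    ia = np.array([idx[a] for a, _ in pairs], dtype=int)
    ib = np.array([idx[b] for _, b in pairs], dtype=int)
    new_rows = np.array([idx[g] for g in new_ids], dtype=int)
    weights_before = {k: v.copy() for k, v in model.state_dict().items()}

    def total_loss_and_grad(Xc):
        X_t = nn.Tensor(Xc, requires_grad=True)
        H = model.gnn.forward(X_t, P)
        s = (H.gather_rows(ia) * H.gather_rows(ib)).sum(axis=1).sigmoid()
        eps = 1e-12
        loss = -((s + eps).log() * labels + (1 - s + eps).log() * (1 - labels)).mean()
        loss.backward()
        return loss.item(), X_t.grad

    def per_node_loss(Xc):
        with nn.no_grad():
            H = model.gnn.forward(nn.Tensor(Xc), P).numpy()
        out = {}
        for g in new_ids:
            pl = [(1, (a, b)) for a, b in inc_pos if g in (a, b)]
            nl = [(0, (a, b)) for a, b in inc_neg if g in (a, b)]
            if not pl and not nl:
                out[g] = np.nan
                continue
            eps = 1e-12
            ll = []
            for y, (a, b) in pl + nl:
                p = predict_link(H[idx[a]], H[idx[b]])
                ll.append(-np.log(p + eps) if y else -np.log(1 - p + eps))
            out[g] = float(np.mean(ll))
        return out

    init_losses = per_node_loss(init_X)
    linked = [g for g in new_ids if any(g in (a, b) for a, b in pairs)]
    unlinked = [g for g in new_ids if g not in linked]
    if unlinked:
        warnings.warn(
            f"genes with no incident training links keep their random "
            f"initialization: {unlinked}"
        )

    if pairs:
        cur_lr = lr
        halvings = 0
        loss_prev, grad = total_loss_and_grad(X)
        for _ in range(steps):
            step_dir = np.zeros_like(X)
            step_dir[new_rows] = grad[new_rows]
            X_try = X - cur_lr * step_dir
            if project_unit_norm:
                norms = np.linalg.norm(X_try[new_rows], axis=1, keepdims=True)
                X_try[new_rows] = X_try[new_rows] / (norms + 1e-12)
            loss_try, grad_try = total_loss_and_grad(X_try)
            if loss_try > loss_prev:
                # step rejected; damp the step size (at most three halvings)
                if halvings < 3:
                    halvings += 1
                    cur_lr *= 0.5
                continue
            X, loss_prev, grad = X_try, loss_try, grad_try

    final_losses = per_node_loss(X)
    weights_after = model.state_dict()
    for k, v in weights_before.items():
        if not np.array_equal(v, weights_after[k]):
            raise AssertionError("model weights changed during feature inference")
    if not np.array_equal(
        np.delete(X, new_rows, axis=0), np.delete(init_X, new_rows, axis=0)
    ):
        raise AssertionError("features of existing genes changed during inference")

    return [
        InferredFeature(
            gene_id=g,
            vector=X[idx[g]].copy(),
            n_steps=steps,
            final_loss=final_losses[g],
            init_loss=init_losses[g],
        )
        for g in new_ids
    ]
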