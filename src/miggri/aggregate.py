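"""Multi-instance aggregation: per-image embeddings -> one gene feature vector.

Three aggregators: per-dimension mean pooling, per-dimension max pooling
(both parameter-free and exactly permutation invariant), and a recurrent
LSTM aggregator whose input order is randomly re-shuffled every training
epoch so that, in expectation, it too is order invariant.  Image embeddings
from all orientations of a gene form one set; the recurrent aggregator
returns its final hidden state.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "AggregatorSpec",
    "MeanAggregator",
    "MaxAggregator",
    "LSTMAggregator",
    "make_aggregator",
    "aggregate",
    "epoch_shuffle",
]


@dataclass
class AggregatorSpec:
    kind: str = "mean"  # mean | max | shuffled_lstm
    hidden_dim: int | None = None  # recurrent only; defaults to the input dim
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("mean", "max", "shuffled_lstm"):
            raise ValueError(f"unknown aggregator kind {self.kind!r}")


class MeanAggregator:
    kind = "mean"
    trainable = False

    def __call__(self, vectors: np.ndarray) -> np.ndarray:
        return np.mean(vectors, axis=0)


class MaxAggregator:
    kind = "max"
    trainable = False

    def __call__(self, vectors: np.ndarray) -> np.ndarray:
        return np.max(vectors, axis=0)


class LSTMAggregator(nn.Module):
    """Unidirectional LSTM over the (shuffled) embedding sequence.

    The output is the final hidden state; hidden_dim defaults to the input
    dimension so downstream shapes are aggregator-agnostic.
    """

    kind = "shuffled_lstm"
    trainable = True

    def __init__(self, input_dim: int, hidden_dim: int, seed: int):
        self.cell = nn.LSTMCell(input_dim, hidden_dim, np.random.default_rng(seed))
        self.hidden_dim = hidden_dim

    def forward(self, xs: nn.Tensor) -> nn.Tensor:
        """(T, input_dim) sequence -> (hidden_dim,) final state, with grads."""
        return self.cell.run(xs)

    def __call__(self, vectors: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return self.forward(nn.Tensor(np.atleast_2d(vectors))).numpy()


def make_aggregator(spec: AggregatorSpec, input_dim: int):
    if spec.kind == "mean":
        return MeanAggregator()
    if spec.kind == "max":
        return MaxAggregator()
    hidden = spec.hidden_dim or input_dim
    return LSTMAggregator(input_dim, hidden, spec.seed)


def aggregate(vectors, spec_or_agg, rng: np.random.Generator | None = None) -> np.ndarray:
    """Collapse a nonempty list of equal-length vectors into one vector.

    For the recurrent kind the list is permuted with ``rng`` (if given)
    before the recurrence runs; pooling kinds ignore ``rng``.
    """
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("aggregate requires a nonempty vector list")
    dims = {v.shape for v in vectors}
    if len(dims) != 1:
        raise ValueError(f"inconsistent vector shapes: {dims}")
    mat = np.stack(vectors)
    agg = (
        spec_or_agg
        if not isinstance(spec_or_agg, AggregatorSpec)
        else make_aggregator(spec_or_agg, mat.shape[1])
    )
    if getattr(agg, "kind", None) == "shuffled_lstm" and rng is not None:
        mat = mat[rng.permutation(len(mat))]
    return agg(mat)


def _gene_rng(gene_id: str, epoch: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, epoch, zlib.crc32(gene_id.encode())])
    )


def epoch_shuffle(gene_sets: dict[str, list], epoch: int, seed: int) -> dict[str, list]:
    """Permute each gene's embedding list; a pure function of (gene, epoch, seed)."""
    out = {}
    for gene_id, items in gene_sets.items():
        perm = _gene_rng(gene_id, epoch, seed).permutation(len(items))
        out[gene_id] = [items[i] for i in perm]
    return out
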