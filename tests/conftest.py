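"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from miggri.data import make_splits
from miggri.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted benchmark: 40 genes, 60 edges, strong sharing."""
    cfg = SimulationConfig(
        n_genes=40, n_tfs=10, n_edges=60, n_archetypes=10,
        pattern_share_prob=0.9, noise_sd=0.02, jitter_px=1, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    return make_splits(small_dataset.graph(), seed=11)


@pytest.fixture(scope="session")
def small_embeddings(small_dataset, small_split):
    """Stage-1 embeddings for the small benchmark (trained briefly)."""
    from miggri.stage1 import EncoderConfig, build_pairs, embed_image_sets, train_encoder

    sets = small_dataset.image_sets()
    pairs = build_pairs(small_split, sets, per_pair_cap=2, seed=3)
    cfg = EncoderConfig(
        backbone="small_cnn", embedding_dim=16, learning_rate=2e-3,
        batch_size=32, epochs=3, seed=3, input_downsample=8,
    )
    encoder, history = train_encoder(pairs, cfg)
    return encoder, embed_image_sets(encoder, sets), history
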