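"""End-to-end convenience: generate (or load) data, run both stages, score.

`run_benchmark` is the one-call version of the full pipeline on the default
synthetic benchmark; tests, examples and the acceptance harness all go
through it so they exercise the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import AggregatorSpec
from .data import GRNGraph, SplitSpec, make_splits
from .metrics import MetricsReport, compute_metrics
from .stage1 import EncoderConfig, build_pairs, embed_image_sets, train_encoder
from .stage2 import GNNConfig, Stage2Model, train_stage2
from .synthetic import SimulationConfig, SyntheticDataset, generate_dataset

__all__ = ["BenchmarkResult", "benchmark_encoder_config", "run_benchmark"]


def benchmark_encoder_config(seed: int = 0, **overrides) -> EncoderConfig:
    """Desk-scale stage-1 settings used by the shipped synthetic benchmark."""
    base = dict(
        backbone="small_cnn", embedding_dim=32, learning_rate=2e-3,
        batch_size=64, epochs=8, input_downsample=4, margin=1.0, seed=seed,
    )
    base.update(overrides)
    return EncoderConfig(**base)


@dataclass
class BenchmarkResult:
    dataset: SyntheticDataset
    graph: GRNGraph
    split: SplitSpec
    image_embeddings: pd.DataFrame
    model: Stage2Model
    predictions: pd.DataFrame
    metrics: MetricsReport
    stage1_history: dict
    stage2_history: dict


def run_benchmark(
    seed: int,
    sim_cfg: SimulationConfig | None = None,
    enc_cfg: EncoderConfig | None = None,
    gnn_cfg: GNNConfig | None = None,
    agg_spec: AggregatorSpec | None = None,
    per_pair_cap: int = 4,
    dataset: SyntheticDataset | None = None,
    image_embeddings: pd.DataFrame | None = None,
) -> BenchmarkResult:
    """Run the full two-stage pipeline on the synthetic benchmark.

    ``seed`` drives everything (data generation, splits, both training
    stages) unless explicit configs override it.  Precomputed ``dataset`` /
    ``image_embeddings`` can be passed to skip the corresponding stage
    (used by ablations that share one stage-1 run).
    """
    sim_cfg = sim_cfg or SimulationConfig(seed=seed)
    ds = dataset if dataset is not None else generate_dataset(sim_cfg)
    graph = ds.graph()
    split = make_splits(graph, seed=seed)

    stage1_history: dict = {}
    if image_embeddings is None:
        enc_cfg = enc_cfg or benchmark_encoder_config(seed=seed)
        sets = ds.image_sets()
        pairs = build_pairs(split, sets, per_pair_cap=per_pair_cap, seed=seed)
        encoder, stage1_history = train_encoder(pairs, enc_cfg)
        image_embeddings = embed_image_sets(encoder, sets)

    gnn_cfg = gnn_cfg or GNNConfig.preset("benchmark", seed=seed)
    if gnn_cfg.feature_mode == "random_init":
        model, preds, stage2_history = train_stage2(graph, split, gnn_cfg)
    else:
        model, preds, stage2_history = train_stage2(
            graph, split, gnn_cfg, image_embeddings=image_embeddings,
            agg_spec=agg_spec or AggregatorSpec(kind="mean"),
        )
    rep = compute_metrics(zip(preds["label"], preds["score"]),
                          threshold=gnn_cfg.decision_threshold)
    return BenchmarkResult(
        dataset=ds, graph=graph, split=split, image_embeddings=image_embeddings,
        model=model, predictions=preds, metrics=rep,
        stage1_history=stage1_history, stage2_history=stage2_history,
    )
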