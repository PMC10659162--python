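"""Core data model: expression images, gene image sets, the known regulatory
graph, and train/validation/test splits of its links.

Conventions
-----------
* Images are grayscale arrays of shape (128, 320) with values in [0, 1];
  darker pixels mean higher expression.  Loading standardizes arbitrary
  inputs (resize + grayscale + [0,1] scaling).
* The graph is undirected for message passing (the dot-product decision is
  symmetric); the regulator (TF) side of each known edge is retained as a
  flag for reporting.
* Splits follow the 20% test / 9:1 train-validation protocol with 1:1
  negative sampling from non-adjacent pairs, disjoint across partitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

IMAGE_HEIGHT = 128
IMAGE_WIDTH = 320
ORIENTATIONS = ("L", "D", "V")

__all__ = [
    "IMAGE_HEIGHT",
    "IMAGE_WIDTH",
    "ORIENTATIONS",
    "ExpressionImage",
    "GeneImageSet",
    "GRNGraph",
    "SplitSpec",
    "load_dataset",
    "make_splits",
    "standardize_pixels",
]


@dataclass
class ExpressionImage:
    """One grayscale image of one gene at one orientation (the atomic instance)."""

    gene_id: str
    orientation: str
    stage: str
    pixels: np.ndarray  # (128, 320) float in [0, 1]

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (IMAGE_HEIGHT, IMAGE_WIDTH):
            raise ValueError(
                f"image for {self.gene_id} has shape {self.pixels.shape}, "
                f"expected {(IMAGE_HEIGHT, IMAGE_WIDTH)}"
            )

    @property
    def signal(self) -> np.ndarray:
        """Expression signal s = 1 - pixel value (larger = more expressed)."""
        return 1.0 - self.pixels


@dataclass
class GeneImageSet:
    """All images of one gene, grouped by orientation (possibly empty)."""

    gene_id: str
    by_orientation: dict[str, list[ExpressionImage]] = field(
        default_factory=lambda: {o: [] for o in ORIENTATIONS}
    )

    def all_images(self) -> list[ExpressionImage]:
        return [im for o in ORIENTATIONS for im in self.by_orientation.get(o, [])]

    @property
    def n_images(self) -> int:
        return len(self.all_images())


class GRNGraph:
    """Known regulatory graph: ordered gene nodes + undirected edge set.

    The adjacency matrix is binary, symmetric, zero-diagonal; node order
    defines matrix row order everywhere downstream.
    """

    def __init__(self, nodes: list[str], edges: list[tuple[str, str]]):
        self.nodes = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        self.index = {g: i for i, g in enumerate(self.nodes)}
        self.tf_flag: dict[frozenset, str] = {}
        edge_set: set[frozenset] = set()
        for tf, tgt in edges:
            if tf == tgt:
                raise ValueError(f"self-loop on {tf}")
            if tf not in self.index or tgt not in self.index:
                raise ValueError(f"edge ({tf}, {tgt}) references unknown gene")
            key = frozenset((tf, tgt))
            if key not in edge_set:
                edge_set.add(key)
                self.tf_flag[key] = tf
        self.edges = sorted(tuple(sorted(e)) for e in edge_set)
        n = len(self.nodes)
        self.adjacency = np.zeros((n, n), dtype=np.int8)
        for a, b in self.edges:
            i, j = self.index[a], self.index[b]
            self.adjacency[i, j] = self.adjacency[j, i] = 1

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / (n * (n - 1))

    def has_edge(self, a: str, b: str) -> bool:
        return bool(self.adjacency[self.index[a], self.index[b]])

    @classmethod
    def from_edge_file(cls, path, extra_nodes: list[str] | None = None) -> "GRNGraph":
        df = pd.read_csv(path, sep="\t")
        if not {"tf", "target"} <= set(df.columns):
            raise ValueError(f"edge list {path} must have columns 'tf' and 'target'")
        nodes = sorted(set(df["tf"]) | set(df["target"]) | set(extra_nodes or []))
        return cls(nodes, list(zip(df["tf"], df["target"])))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SplitSpec:
    """Positive and sampled-negative link partitions; leak-free by construction."""

    train_pos: list[tuple[str, str]]
    val_pos: list[tuple[str, str]]
    test_pos: list[tuple[str, str]]
    train_neg: list[tuple[str, str]]
    val_neg: list[tuple[str, str]]
    test_neg: list[tuple[str, str]]
    seed: int

    def __post_init__(self):
        self.assert_leak_free()

    def partitions(self):
        return {
            "train": (self.train_pos, self.train_neg),
            "val": (self.val_pos, self.val_neg),
            "test": (self.test_pos, self.test_neg),
        }

    def assert_leak_free(self) -> None:
        pos = [set(map(frozenset, p)) for p in (self.train_pos, self.val_pos, self.test_pos)]
        neg = [set(map(frozenset, p)) for p in (self.train_neg, self.val_neg, self.test_neg)]
        all_pos = pos[0] | pos[1] | pos[2]
        for i in range(3):
            for j in range(i + 1, 3):
                if pos[i] & pos[j] or neg[i] & neg[j]:
                    raise ValueError("split partitions overlap")
        for n in neg:
            if n & all_pos:
                raise ValueError("negative pair coincides with a known edge")

    def to_json(self, path) -> None:
        payload = {"seed": self.seed}
        for name in ("train_pos", "val_pos", "test_pos", "train_neg", "val_neg", "test_neg"):
            payload[name] = [list(p) for p in getattr(self, name)]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SplitSpec":
        payload = json.loads(Path(path).read_text())
        kwargs = {
            name: [tuple(p) for p in payload[name]]
            for name in ("train_pos", "val_pos", "test_pos", "train_neg", "val_neg", "test_neg")
        }
        return cls(seed=payload["seed"], **kwargs)


def make_splits(
    graph: GRNGraph,
    seed: int,
    exclude: list[tuple[str, str]] | None = None,
) -> SplitSpec:
    """Partition known links 72/8/20 (train/val/test) and sample 1:1 negatives.

    Test takes round(0.2|E|) links; the remainder splits 9:1 into train and
    validation (rounding half away from zero, remainder to train).  Negatives
    are drawn uniformly without replacement from unordered non-adjacent
    pairs, disjoint across partitions; ``exclude`` removes additional pairs
    (e.g. medium-confidence links) from the negative universe.
    """
    if graph.n_edges < 10:
        raise ValueError("need at least 10 known links to split")
    rng = np.random.default_rng(seed)
    edges = list(graph.edges)
    perm = rng.permutation(len(edges))
    edges = [edges[i] for i in perm]

    n = len(edges)
    n_test = _round_half_up(0.2 * n)
    n_val = _round_half_up(0.1 * (n - n_test))
    test_pos = edges[:n_test]
    val_pos = edges[n_test : n_test + n_val]
    train_pos = edges[n_test + n_val :]

    known = set(map(frozenset, graph.edges))
    banned = known | set(map(frozenset, exclude or []))
    nodes = graph.nodes
    non_edges = [
        (nodes[i], nodes[j])
        for i in range(len(nodes))
        for j in range(i + 1, len(nodes))
        if frozenset((nodes[i], nodes[j])) not in banned
    ]
    if len(non_edges) < n:
        raise ValueError("graph too dense: not enough non-edges for negative sampling")
    neg_idx = rng.choice(len(non_edges), size=n, replace=False)
    negs = [non_edges[i] for i in neg_idx]
    test_neg = negs[:n_test]
    val_neg = negs[n_test : n_test + n_val]
    train_neg = negs[n_test + n_val :]

    return SplitSpec(
        train_pos=train_pos, val_pos=val_pos, test_pos=test_pos,
        train_neg=train_neg, val_neg=val_neg, test_neg=test_neg, seed=seed,
    )


# ---------------------------------------------------------------------------
# loading


def standardize_pixels(arr: np.ndarray) -> np.ndarray:
    """Resize to 320x128, grayscale, scale to [0, 1]."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.max() > 1.0:
        arr = arr / 255.0
    if arr.shape != (IMAGE_HEIGHT, IMAGE_WIDTH):
        im = Image.fromarray((np.clip(arr, 0, 1) * 255).astype(np.uint8))
        im = im.resize((IMAGE_WIDTH, IMAGE_HEIGHT), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float64) / 255.0
    return np.clip(arr, 0.0, 1.0)


def load_dataset(
    manifest_path, image_dir, edge_path
) -> tuple[dict[str, GeneImageSet], GRNGraph]:
    """Read a manifest + image directory + edge list into the data model.

    Genes named in the edge list but absent from the manifest get empty
    image sets (the missing-data case) rather than an error.
    """
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"gene_id", "orientation", "stage", "file_path"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest missing columns {required - set(manifest.columns)}")
    image_dir = Path(image_dir)

    sets: dict[str, GeneImageSet] = {}
    for row in manifest.itertuples(index=False):
        orient = str(row.orientation)
        if orient not in ORIENTATIONS:
            raise ValueError(f"unknown orientation token {orient!r} in manifest")
        path = image_dir / str(row.file_path)
        try:
            with Image.open(path) as im:
                arr = np.asarray(im)
        except Exception as exc:  # noqa: BLE001 - re-raise naming the file
            raise OSError(f"unreadable image file {path}") from exc
        img = ExpressionImage(
            gene_id=str(row.gene_id),
            orientation=orient,
            stage=str(row.stage),
            pixels=standardize_pixels(arr),
        )
        sets.setdefault(img.gene_id, GeneImageSet(img.gene_id)).by_orientation[
            orient
        ].append(img)

    graph = GRNGraph.from_edge_file(edge_path, extra_nodes=sorted(sets))
    for gene in graph.nodes:
        sets.setdefault(gene, GeneImageSet(gene))
    return sets, graph
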