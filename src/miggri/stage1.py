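"""Stage 1: siamese convolutional feature extraction with a contrastive loss.

Image pairs are built from labeled gene pairs: for each pair of genes and
each orientation both genes have images for, the Cartesian product of their
images yields training pairs carrying the gene-pair label (1 = interacting).
Pairs never mix orientations and a gene is never paired with itself.  One
shared-weight encoder embeds both pair members; the contrastive loss pulls
interacting pairs together and pushes non-interacting pairs beyond a margin
``m``:

    L = 1/2 ||x_a - x_b||^2              if y = 1
    L = 1/2 max(0, m - ||x_a - x_b||)^2  if y = 0

After training, every image is embedded once and the per-image vectors are
handed to the multi-instance aggregation of stage 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .data import ORIENTATIONS, ExpressionImage, GeneImageSet, SplitSpec

__all__ = [
    "ImagePair",
    "EncoderConfig",
    "build_pairs",
    "contrastive_loss",
    "train_encoder",
    "embed_image_sets",
    "save_encoder",
    "load_encoder",
    "SmallCNN",
    "ModifiedVGG",
]


@dataclass
class ImagePair:
    img_a: ExpressionImage
    img_b: ExpressionImage
    label: int  # 1 = interacting gene pair, 0 = sampled non-interacting

    def __post_init__(self):
        if self.img_a.orientation != self.img_b.orientation:
            raise ValueError("pair members must share an orientation")
        if self.img_a.gene_id == self.img_b.gene_id:
            raise ValueError("a gene is never paired with itself")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class EncoderConfig:
    backbone: str = "small_cnn"  # or "vgg16_modified"
    embedding_dim: int = 128
    margin: float = 1.0
    learning_rate: float = 5e-6
    batch_size: int = 16
    epochs: int = 50
    seed: int = 0
    input_downsample: int = 4  # block-mean factor applied before the CNN

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.backbone not in ("small_cnn", "vgg16_modified"):
            raise ValueError(f"unknown backbone {self.backbone!r}")

    @classmethod
    def preset(cls, name: str, **overrides) -> "EncoderConfig":
        """Named hyperparameter presets for the two reference networks."""
        presets = {
            "eye": dict(backbone="vgg16_modified", learning_rate=5e-6,
                        batch_size=16, epochs=50, margin=1.0),
            "mesoderm": dict(backbone="vgg16_modified", learning_rate=5e-6,
                             batch_size=32, epochs=22, margin=1.0),
        }
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}")
        return cls(**{**presets[name], **overrides})


# ---------------------------------------------------------------------------
# loss


def contrastive_loss(x_a: np.ndarray, x_b: np.ndarray, y: int, m: float) -> float:
    """Closed-form contrastive loss for a single pair of embedding vectors."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if x_a.shape != x_b.shape:
        raise ValueError(f"dimension mismatch: {x_a.shape} vs {x_b.shape}")
    if m <= 0:
        raise ValueError("margin must be positive")
    d = float(np.linalg.norm(x_a - x_b))
    if y == 1:
        return 0.5 * d * d
    if y == 0:
        return 0.5 * max(0.0, m - d) ** 2
    raise ValueError("label must be 0 or 1")


# ---------------------------------------------------------------------------
# pair construction


def build_pairs(
    split: SplitSpec,
    image_sets: dict[str, GeneImageSet],
    per_pair_cap: int = 8,
    seed: int = 0,
    partition: str = "train",
) -> list[ImagePair]:
    """Enumerate same-orientation image pairs for one split partition.

    For each labeled gene pair and orientation the Cartesian product of the
    two genes' images is enumerated; products larger than ``per_pair_cap``
    are subsampled uniformly with the given seed.  Gene pairs sharing no
    orientation contribute nothing.
    """
    rng = np.random.default_rng(seed)
    pos, neg = split.partitions()[partition]
    pairs: list[ImagePair] = []
    for label, gene_pairs in ((1, pos), (0, neg)):
        for ga, gb in gene_pairs:
            sa = image_sets.get(ga)
            sb = image_sets.get(gb)
            if sa is None or sb is None:
                continue
            for o in ORIENTATIONS:
                ims_a = sa.by_orientation.get(o, [])
                ims_b = sb.by_orientation.get(o, [])
                combos = [(ia, ib) for ia in ims_a for ib in ims_b]
                if len(combos) > per_pair_cap:
                    idx = rng.choice(len(combos), size=per_pair_cap, replace=False)
                    combos = [combos[i] for i in sorted(idx)]
                pairs.extend(ImagePair(ia, ib, label) for ia, ib in combos)
    return pairs


# ---------------------------------------------------------------------------
# encoders


def _block_mean(x: np.ndarray, f: int) -> np.ndarray:
    """Downsample (N, H, W) by block-averaging f x f patches."""
    if f == 1:
        return x
    n, h, w = x.shape
    return x.reshape(n, h // f, f, w // f, f).mean(axis=(2, 4))


class SmallCNN(nn.Module):
    """Three stride-2 conv blocks + flattened linear head.

    The head flattens the final feature map instead of pooling it away:
    expression patterns differ mainly in WHERE intensity sits, so spatial
    position must survive into the embedding.  Desk-scale default backbone.
    """

    def __init__(self, embedding_dim: int, rng: np.random.Generator,
                 input_hw: tuple[int, int] = (32, 80)):
        self.conv1 = nn.Conv2d(1, 8, 3, rng, stride=2, pad=1)
        self.conv2 = nn.Conv2d(8, 16, 3, rng, stride=2, pad=1)
        self.conv3 = nn.Conv2d(16, 32, 3, rng, stride=2, pad=1)
        h, w = input_hw
        self._flat = 32 * (h // 8) * (w // 8)
        self.head = nn.Linear(self._flat, embedding_dim, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        return self.head(h.reshape((x.shape[0], self._flat)))


class ModifiedVGG(nn.Module):
    """VGG-style stack truncated after four blocks, GAP, linear projection.

    Channel widths 32-64-128-256 (half-width VGG-16); each block is two 3x3
    convolutions with the first at stride 2 in place of pooling.
    """

    def __init__(self, embedding_dim: int, rng: np.random.Generator):
        chans = [(1, 32), (32, 64), (64, 128), (128, 256)]
        self.blocks = []
        for c_in, c_out in chans:
            self.blocks.append(nn.Conv2d(c_in, c_out, 3, rng, stride=2, pad=1))
            self.blocks.append(nn.Conv2d(c_out, c_out, 3, rng, stride=1, pad=1))
        self.head = nn.Linear(256, embedding_dim, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = x
        for conv in self.blocks:
            h = conv(h).relu()
        pooled = h.mean(axis=3).mean(axis=2)
        return self.head(pooled)


class Encoder:
    """Shared-weight tower: preprocessing + backbone CNN."""

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.input_downsample
        from .data import IMAGE_HEIGHT, IMAGE_WIDTH

        if cfg.backbone == "small_cnn":
            self.net = SmallCNN(
                cfg.embedding_dim, rng, input_hw=(IMAGE_HEIGHT // f, IMAGE_WIDTH // f)
            )
        else:
            self.net = ModifiedVGG(cfg.embedding_dim, rng)

    def preprocess(self, images: np.ndarray) -> np.ndarray:
        """(N, H, W) pixel arrays -> (N, 1, h, w) expression-signal inputs."""
        sig = 1.0 - np.asarray(images, dtype=np.float64)  # darker = higher
        sig = _block_mean(sig, self.cfg.input_downsample)
        return sig[:, None, :, :]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.net.forward(x)

    def embed(self, images: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Embed raw (N, H, W) images without building a graph."""
        x = self.preprocess(images)
        outs = []
        with nn.no_grad():
            for i in range(0, len(x), chunk):
                outs.append(self.forward(nn.Tensor(x[i : i + chunk])).numpy())
        return np.concatenate(outs, axis=0) if outs else np.zeros((0, self.cfg.embedding_dim))

    def parameters(self):
        return self.net.parameters()


# ---------------------------------------------------------------------------
# training


def _interleaved_batches(pos_idx, neg_idx, batch_size, rng):
    """1:1 positive/negative interleaving per batch (dataset-level balance)."""
    pos = rng.permutation(pos_idx)
    neg = rng.permutation(neg_idx)
    half = max(1, batch_size // 2)
    n_batches = int(np.ceil(max(len(pos), len(neg)) / half))
    for b in range(n_batches):
        chunk = np.concatenate([pos[b * half : (b + 1) * half], neg[b * half : (b + 1) * half]])
        if len(chunk):
            yield chunk


def _pair_batch_loss(emb: nn.Tensor, a_rows, b_rows, labels, m: float) -> nn.Tensor:
    ea = emb.gather_rows(a_rows)
    eb = emb.gather_rows(b_rows)
    d2 = ((ea - eb) ** 2).sum(axis=1)
    d = (d2 + 1e-12).sqrt()
    pos_term = 0.5 * d2
    neg_term = 0.5 * ((m - d).relu() ** 2)
    y = np.asarray(labels, dtype=float)
    return (pos_term * y + neg_term * (1.0 - y)).mean()


def train_encoder(
    pairs: list[ImagePair],
    cfg: EncoderConfig,
    val_pairs: list[ImagePair] | None = None,
) -> tuple[Encoder, dict]:
    """Train the siamese encoder on image pairs; returns (encoder, history).

    Each minibatch embeds its unique images once and gathers rows for both
    pair members, so weight sharing between the towers is structural.  The
    training-loss trajectory (and validation loss, if given) is logged per
    epoch; the epoch with the best validation loss is recorded in the
    history.
    """
    if not pairs:
        raise ValueError("train_encoder requires a nonempty pair list")
    encoder = Encoder(cfg)
    rng = np.random.default_rng(cfg.seed + 1)

    # index unique image objects
    images: list[ExpressionImage] = []
    idx_of: dict[int, int] = {}
    for p in pairs:
        for im in (p.img_a, p.img_b):
            if id(im) not in idx_of:
                idx_of[id(im)] = len(images)
                images.append(im)
    stack = encoder.preprocess(np.stack([im.pixels for im in images]))
    a_idx = np.array([idx_of[id(p.img_a)] for p in pairs])
    b_idx = np.array([idx_of[id(p.img_b)] for p in pairs])
    labels = np.array([p.label for p in pairs])
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)

    opt = nn.Adam(encoder.parameters(), lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": [], "best_val_epoch": None}
    best_val = np.inf
    for epoch in range(cfg.epochs):
        losses = []
        for batch in _interleaved_batches(pos_idx, neg_idx, cfg.batch_size, rng):
            uniq, inv = np.unique(np.concatenate([a_idx[batch], b_idx[batch]]), return_inverse=True)
            emb = encoder.forward(nn.Tensor(stack[uniq]))
            nb = len(batch)
            loss = _pair_batch_loss(emb, inv[:nb], inv[nb:], labels[batch], cfg.margin)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite contrastive loss at epoch {epoch}; "
                    "reduce the learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_loss"].append(float(np.mean(losses)))
        if val_pairs:
            v = evaluate_pair_loss(encoder, val_pairs, cfg.margin)
            history["val_loss"].append(v)
            if v < best_val:
                best_val = v
                history["best_val_epoch"] = epoch
    return encoder, history


def evaluate_pair_loss(encoder: Encoder, pairs: list[ImagePair], m: float) -> float:
    """Mean contrastive loss of an encoder over a pair list (no training)."""
    images, idx_of = [], {}
    for p in pairs:
        for im in (p.img_a, p.img_b):
            if id(im) not in idx_of:
                idx_of[id(im)] = len(images)
                images.append(im)
    emb = encoder.embed(np.stack([im.pixels for im in images]))
    losses = [
        contrastive_loss(emb[idx_of[id(p.img_a)]], emb[idx_of[id(p.img_b)]], p.label, m)
        for p in pairs
    ]
    return float(np.mean(losses))


def embed_image_sets(
    encoder: Encoder, image_sets: dict[str, GeneImageSet]
) -> pd.DataFrame:
    """One embedding row per image: gene_id, orientation, image_index, v0..vD-1."""
    rows, arrays = [], []
    for gene in sorted(image_sets):
        for o in ORIENTATIONS:
            for k, im in enumerate(image_sets[gene].by_orientation.get(o, [])):
                rows.append((gene, o, k))
                arrays.append(im.pixels)
    if arrays:
        vecs = encoder.embed(np.stack(arrays))
    else:
        vecs = np.zeros((0, encoder.cfg.embedding_dim))
    if not np.all(np.isfinite(vecs)):
        raise FloatingPointError("non-finite image embedding")
    df = pd.DataFrame(rows, columns=["gene_id", "orientation", "image_index"])
    for j in range(vecs.shape[1]):
        df[f"v{j}"] = vecs[:, j]
    return df


def save_encoder(encoder: Encoder, path) -> None:
    """Checkpoint as .npz (weights) + .json sidecar (config)."""
    path = Path(path)
    np.savez(path, **encoder.net.state_dict())
    path.with_suffix(".json").write_text(json.dumps(asdict(encoder.cfg), indent=1))


def load_encoder(path) -> Encoder:
    path = Path(path)
    cfg = EncoderConfig(**json.loads(path.with_suffix(".json").read_text()))
    encoder = Encoder(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        encoder.net.load_state_dict({k: z[k] for k in z.files})
    return encoder
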