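"""Per-orientation deconvolutional decoders: gene feature vector -> image.

One decoder per orientation (views differ too much to share weights).  The
latent vector seeds an 8x20 spatial map which four transposed-convolution
blocks (kernel 4, stride 2, pad 1 — exact doubling) upsample to 128x320.
Each block carries an additive residual branch (nearest-neighbour x2
upsampling + 1x1 convolution); a final sigmoid keeps pixels in [0, 1].
Training minimizes mean-squared error against the per-gene mean image of
the orientation (the MSE-optimal single target when a gene has several
images).  Decoding the gradient-inferred features of genes that were held
out of the training graph yields their "recovered" expression patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .data import IMAGE_HEIGHT, IMAGE_WIDTH, GeneImageSet

__all__ = ["DecoderConfig", "ReconstructedImage", "Decoder", "train_decoder", "reconstruct"]

@dataclass
class DecoderConfig:
    orientation: str
    latent_dim: int
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 2e-4
    seed: int = 0
    base_channels: int = 128  # channels at the spatial seed; halve per block
    seed_hw: tuple[int, int] = (8, 20)  # spatial seed; x16 through the 4 blocks
    feature_noise_sd: float = 0.0  # latent jitter during training (regularizer)

    def __post_init__(self):
        if self.orientation not in ("L", "D", "V"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.base_channels < 16:
            raise ValueError("base_channels must be at least 16")
        h, w = self.seed_hw
        if IMAGE_HEIGHT % (16 * h) or IMAGE_WIDTH % (16 * w):
            raise ValueError("seed_hw x16 must divide the 128x320 output")


@dataclass
class ReconstructedImage:
    gene_id: str
    orientation: str
    pixels: np.ndarray  # (128, 320) in [0, 1]
    mse_vs_reference: float | None = None


class _UpBlock(nn.Module):
    """Transposed conv (x2 upsample) with an additive residual branch.

    Kernel 2 / stride 2 tiles the output exactly (no overlap), which keeps
    the im2col buffers at high resolution four times smaller than the
    overlapping kernel-4 variant.
    """

    def __init__(self, c_in: int, c_out: int, rng):
        self.deconv = nn.ConvTranspose2d(c_in, c_out, 2, rng, stride=2, pad=0)
        self.skip = nn.Conv2d(c_in, c_out, 1, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        # nearest-neighbour x2 upsampling via broadcasting
        up = (x.reshape((n, c, h, 1, w, 1)) * np.ones((1, 1, 1, 2, 1, 2))).reshape(
            (n, c, 2 * h, 2 * w)
        )
        return (self.deconv(x) + self.skip(up)).relu()


class Decoder(nn.Module):
    def __init__(self, cfg: DecoderConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c0 = cfg.base_channels
        sh, sw = cfg.seed_hw
        self.fc = nn.Linear(cfg.latent_dim, c0 * sh * sw, rng)
        chans = [c0, c0 // 2, c0 // 4, c0 // 8, max(c0 // 8, 8)]
        self.blocks = [
            _UpBlock(chans[i], chans[i + 1], rng) for i in range(4)
        ]
        self.out_conv = nn.Conv2d(chans[4], 1, 3, rng, stride=1, pad=1)
        # parameter-free nearest upsampling from the blocks' native
        # resolution to 128 x 320 (1 with the default 8x20 seed)
        self._upsample = IMAGE_HEIGHT // (16 * sh)

    def forward(self, z: nn.Tensor) -> nn.Tensor:
        """(N, latent_dim) -> (N, 128, 320) pixel images in (0, 1)."""
        n = z.shape[0]
        sh, sw = self.cfg.seed_hw
        h = self.fc(z).relu().reshape((n, self.cfg.base_channels, sh, sw))
        for blk in self.blocks:
            h = blk(h)
        out = self.out_conv(h).sigmoid()
        f = self._upsample
        if f > 1:
            _, c, hh, ww = out.shape
            out = (out.reshape((n, c, hh, 1, ww, 1)) * np.ones((1, 1, 1, f, 1, f))
                   ).reshape((n, c, hh * f, ww * f))
        return out.reshape((n, IMAGE_HEIGHT, IMAGE_WIDTH))


def _mean_image(images) -> np.ndarray:
    return np.mean([im.pixels for im in images], axis=0)


def train_decoder(
    features: dict[str, np.ndarray],
    image_sets: dict[str, GeneImageSet] | None,
    cfg: DecoderConfig,
    targets: dict[str, np.ndarray] | None = None,
) -> tuple[Decoder, dict]:
    """Train one orientation's decoder on genes that have both a feature and
    at least one image of that orientation; returns (decoder, history).

    ``features`` must not contain held-out (unseen) genes — excluding them
    is the caller's responsibility and is what makes decoded unseen genes a
    genuine reconstruction test.  ``targets`` can supply explicit target
    images per feature key instead of ``image_sets`` (used when several
    feature samples of one gene share a target).
    """
    if targets is not None:
        genes = sorted(g for g in features if g in targets)
        if not genes:
            raise ValueError(f"no training images for orientation {cfg.orientation!r}")
        Y = np.stack([np.asarray(targets[g], dtype=float) for g in genes])
    else:
        genes = sorted(
            g for g, s in image_sets.items()
            if g in features and s.by_orientation.get(cfg.orientation)
        )
        if not genes:
            raise ValueError(f"no training images for orientation {cfg.orientation!r}")
        Y = np.stack([_mean_image(image_sets[g].by_orientation[cfg.orientation]) for g in genes])
    Z = np.stack([np.asarray(features[g], dtype=float) for g in genes])

    decoder = Decoder(cfg)
    opt = nn.Adam(decoder.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = {"train_mse": [], "orientation": cfg.orientation, "n_genes": len(genes)}
    for _ in range(cfg.epochs):
        order = rng.permutation(len(genes))
        losses = []
        for i in range(0, len(genes), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            z = Z[sel]
            if cfg.feature_noise_sd > 0:
                z = z + rng.normal(0.0, cfg.feature_noise_sd, size=z.shape)
            pred = decoder.forward(nn.Tensor(z))
            loss = ((pred - Y[sel]) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history["train_mse"].append(float(np.mean(losses)))
    return decoder, history


def reconstruct(
    decoder: Decoder, feature: np.ndarray, gene_id: str = "?",
    reference: np.ndarray | None = None,
) -> ReconstructedImage:
    """Decode one feature vector into an expression image (deterministic)."""
    z = np.asarray(feature, dtype=float).reshape(1, -1)
    if z.shape[1] != decoder.cfg.latent_dim:
        raise ValueError(
            f"feature dim {z.shape[1]} != decoder latent dim {decoder.cfg.latent_dim}"
        )
    with nn.no_grad():
        pixels = decoder.forward(nn.Tensor(z)).numpy()[0]
    mse = float(np.mean((pixels - reference) ** 2)) if reference is not None else None
    return ReconstructedImage(
        gene_id=gene_id, orientation=decoder.cfg.orientation,
        pixels=np.clip(pixels, 0.0, 1.0), mse_vs_reference=mse,
    )
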