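"""Synthetic embryo-image benchmark with a planted regulatory network.

The generator emulates the structure of standardized in-situ hybridization
collections: each gene owns a small set of 320x128 grayscale images per
orientation (lateral / dorsal / ventral), pixel intensity encodes expression
(darker = higher), and only a sparse partial network of TF->target links is
"known".  The planted signal is pattern sharing: genes draw their spatial
expression patterns from a pool of archetypes (sets of Gaussian blobs inside
an elliptical embryo mask), and with probability ``pattern_share_prob`` an
interacting pair is forced to share at least one archetype.  Image pairs of
interacting genes therefore correlate more strongly than random pairs, which
is exactly the signal the contrastive stage is meant to pick up.

Orientations are deterministic transforms of the lateral pattern (dorsal =
vertical mirror; ventral = mirror + 8 px horizontal shift), so the
same-orientation pairing constraint of stage 1 has something real to
respect.  Generation is a pure function of the config, including its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data import IMAGE_HEIGHT, IMAGE_WIDTH, ExpressionImage, GeneImageSet, GRNGraph

__all__ = [
    "PatternArchetype",
    "SimulationConfig",
    "SyntheticDataset",
    "embryo_mask",
    "embryo_canvas",
    "render_image",
    "generate_dataset",
    "write_dataset",
]

MASK_MARGIN = 6  # px between the ellipse and the frame
EMBRYO_SHADE = 0.05  # how much darker the embryo body is than the background
STAGE_LABEL = "13-16"  # last embryonic phase; no multi-stage simulation
VENTRAL_SHIFT = 8  # px horizontal offset of the ventral view


@dataclass(frozen=True)
class PatternArchetype:
    """A reusable spatial expression pattern: Gaussian blobs inside the embryo."""

    archetype_id: int
    blob_centers: tuple[tuple[float, float], ...]  # (row, col)
    blob_widths: tuple[float, ...]  # Gaussian sigma, px
    base_intensity: float  # in [0, 1]

    def __post_init__(self):
        if any(w <= 0 for w in self.blob_widths):
            raise ValueError("blob widths must be strictly positive")
        if len(self.blob_centers) != len(self.blob_widths):
            raise ValueError("one width per blob center required")
        mask = embryo_mask()
        for r, c in self.blob_centers:
            if not mask[int(round(r)), int(round(c))]:
                raise ValueError(f"blob center ({r}, {c}) outside the embryo mask")


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_tfs: int = 40
    n_edges: int = 600
    n_archetypes: int = 24
    images_per_orientation: tuple[int, int] = (1, 3)
    pattern_share_prob: float = 0.8
    noise_sd: float = 0.05
    jitter_px: int = 3
    missing_gene_frac: float = 0.0
    orientations: tuple[str, ...] = ("L", "D", "V")
    seed: int = 0
    image_height: int = IMAGE_HEIGHT
    image_width: int = IMAGE_WIDTH

    def validate(self) -> None:
        if self.n_edges > self.n_tfs * (self.n_genes - 1):
            raise ValueError(
                f"n_edges={self.n_edges} exceeds the bipartite bound "
                f"{self.n_tfs * (self.n_genes - 1)}"
            )
        if not (
            isinstance(self.image_height, int)
            and isinstance(self.image_width, int)
            and self.image_height > 0
            and self.image_width > 0
        ):
            raise ValueError("image dimensions must be positive integers")
        if (self.image_height, self.image_width) != (IMAGE_HEIGHT, IMAGE_WIDTH):
            raise ValueError(
                f"generator renders standardized {IMAGE_WIDTH}x{IMAGE_HEIGHT} images"
            )
        if not 0.0 <= self.missing_gene_frac < 1.0:
            raise ValueError("missing_gene_frac must be in [0, 1)")
        if not 0.0 <= self.pattern_share_prob <= 1.0:
            raise ValueError("pattern_share_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.jitter_px < 0:
            raise ValueError("noise_sd and jitter_px must be nonnegative")
        lo, hi = self.images_per_orientation
        if not 1 <= lo <= hi:
            raise ValueError("images_per_orientation must satisfy 1 <= min <= max")
        for o in self.orientations:
            if o not in ("L", "D", "V"):
                raise ValueError(f"unknown orientation {o!r}")


@dataclass
class SyntheticDataset:
    images: list[ExpressionImage]
    manifest: pd.DataFrame  # gene_id, orientation, stage, file_path
    edges: list[tuple[str, str]]  # (tf, target)
    gene_archetypes: dict[str, tuple[int, ...]]  # ground truth, for tests
    archetypes: list[PatternArchetype]
    missing_genes: list[str]
    config: SimulationConfig

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_archetypes)

    @property
    def density(self) -> float:
        n = len(self.genes)
        return 2.0 * len(self.edges) / (n * (n - 1))

    def graph(self) -> GRNGraph:
        return GRNGraph(self.genes, self.edges)

    def image_sets(self) -> dict[str, GeneImageSet]:
        sets = {g: GeneImageSet(g) for g in self.genes}
        for img in self.images:
            sets[img.gene_id].by_orientation[img.orientation].append(img)
        return sets


# ---------------------------------------------------------------------------
# rendering


def embryo_mask(height: int = IMAGE_HEIGHT, width: int = IMAGE_WIDTH) -> np.ndarray:
    """Boolean ellipse inscribed in the frame with a 6 px margin."""
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry, rx = height / 2.0 - MASK_MARGIN, width / 2.0 - MASK_MARGIN
    yy, xx = np.mgrid[0:height, 0:width]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def embryo_canvas(height: int = IMAGE_HEIGHT, width: int = IMAGE_WIDTH) -> np.ndarray:
    """The blank embryo image: light background, faintly darker embryo body."""
    return 1.0 - EMBRYO_SHADE * embryo_mask(height, width)


def _orient_centers(
    centers: np.ndarray, orientation: str, height: int
) -> np.ndarray:
    out = centers.copy()
    if orientation in ("D", "V"):
        out[:, 0] = (height - 1) - out[:, 0]  # vertical mirror of the lateral view
    if orientation == "V":
        out[:, 1] = out[:, 1] + VENTRAL_SHIFT
    return out


def render_image(
    archetypes,
    orientation: str,
    noise_sd: float,
    jitter_px: int,
    rng: np.random.Generator,
    height: int = IMAGE_HEIGHT,
    width: int = IMAGE_WIDTH,
) -> np.ndarray:
    """Render one image: Gaussian expression blobs subtracted from the canvas.

    Returns a (height, width) array in [0, 1]; darker = higher expression.
    Jitter and noise draw from ``rng``; with noise_sd=0 and jitter_px=0 the
    output is a deterministic function of the archetypes and orientation.
    """
    archetypes = list(archetypes)
    if not archetypes:
        raise ValueError("render_image requires a nonempty archetype set")
    if orientation not in ("L", "D", "V"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mask = embryo_mask(height, width)
    canvas = 1.0 - EMBRYO_SHADE * mask
    if jitter_px > 0:
        dy, dx = rng.integers(-jitter_px, jitter_px + 1, size=2)
    else:
        dy = dx = 0
    yy, xx = np.mgrid[0:height, 0:width]
    depth = np.zeros((height, width))
    for arch in archetypes:
        centers = _orient_centers(
            np.asarray(arch.blob_centers, dtype=float), orientation, height
        )
        for (cy, cx), w in zip(centers, arch.blob_widths):
            d2 = (yy - (cy + dy)) ** 2 + (xx - (cx + dx)) ** 2
            depth += arch.base_intensity * np.exp(-d2 / (2.0 * w**2))
    pixels = canvas - depth * mask
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    return np.clip(pixels, 0.0, 1.0)


# ---------------------------------------------------------------------------
# generation


def _sample_archetypes(cfg: SimulationConfig, rng: np.random.Generator):
    mask = embryo_mask(cfg.image_height, cfg.image_width)
    inside = np.argwhere(mask)
    archetypes = []
    for k in range(cfg.n_archetypes):
        n_blobs = int(rng.integers(1, 4))
        centers = tuple(
            tuple(inside[i].astype(float)) for i in rng.integers(0, len(inside), n_blobs)
        )
        widths = tuple(rng.uniform(10.0, 26.0, size=n_blobs))
        base = float(rng.uniform(0.45, 0.9))
        archetypes.append(
            PatternArchetype(
                archetype_id=k, blob_centers=centers, blob_widths=widths,
                base_intensity=base,
            )
        )
    return archetypes


def _sample_edges(cfg: SimulationConfig, genes, rng: np.random.Generator):
    """TF out-degrees follow a truncated power law so hub regulators exist."""
    tfs = genes[: cfg.n_tfs]
    weights = np.arange(1, cfg.n_tfs + 1, dtype=float) ** -0.8
    weights /= weights.sum()
    chosen: dict[str, set[str]] = {tf: set() for tf in tfs}
    edges: list[tuple[str, str]] = []
    while len(edges) < cfg.n_edges:
        tf = tfs[int(rng.choice(cfg.n_tfs, p=weights))]
        if len(chosen[tf]) >= cfg.n_genes - 1:
            continue
        tgt = genes[int(rng.integers(0, cfg.n_genes))]
        if tgt == tf or tgt in chosen[tf] or tf in chosen.get(tgt, set()):
            continue
        chosen[tf].add(tgt)
        edges.append((tf, tgt))
    return edges


def generate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full benchmark; a pure function of ``cfg`` (incl. seed)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = int(np.ceil(np.log10(max(cfg.n_genes, 10))))
    genes = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]
    archetypes = _sample_archetypes(cfg, rng)
    edges = _sample_edges(cfg, genes, rng)

    # Per-gene archetype sets (1-3 per gene, most genes a single coherent
    # domain), then pattern sharing along planted edges: each edge is
    # flagged for sharing with probability pattern_share_prob, and a
    # target's set is rebuilt to contain one archetype from EACH of its
    # flagged regulators (up to the 3-archetype cap), so overlap survives
    # multiple regulators instead of each edge overwriting the last.
    assign = {
        g: [int(a) for a in rng.choice(
            cfg.n_archetypes,
            size=int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1])),
            replace=False,
        )]
        for g in genes
    }
    donors: dict[str, list[str]] = {}
    for tf, tgt in edges:
        if rng.uniform() < cfg.pattern_share_prob:
            donors.setdefault(tgt, []).append(tf)
    for tgt in genes:
        tf_list = donors.get(tgt)
        if not tf_list:
            continue
        inherited: list[int] = []
        for tf in tf_list[:3]:
            pick = int(assign[tf][int(rng.integers(0, len(assign[tf])))])
            if pick not in inherited:
                inherited.append(pick)
        keep = [a for a in assign[tgt] if a not in inherited]
        assign[tgt] = (inherited + keep)[: max(len(inherited), len(assign[tgt]))][:3]

    n_missing = int(round(cfg.missing_gene_frac * cfg.n_genes))
    missing = sorted(rng.choice(genes, size=n_missing, replace=False).tolist())
    missing_set = set(missing)

    lo, hi = cfg.images_per_orientation
    images: list[ExpressionImage] = []
    rows = []
    for g in genes:
        if g in missing_set:
            continue
        archs = [archetypes[k] for k in assign[g]]
        for orient in cfg.orientations:
            n_img = int(rng.integers(lo, hi + 1))
            for idx in range(n_img):
                pixels = render_image(
                    archs, orient, cfg.noise_sd, cfg.jitter_px, rng,
                    cfg.image_height, cfg.image_width,
                )
                fname = f"{g}_{orient}_{idx}.png"
                images.append(ExpressionImage(g, orient, STAGE_LABEL, pixels))
                rows.append((g, orient, STAGE_LABEL, fname))

    manifest = pd.DataFrame(rows, columns=["gene_id", "orientation", "stage", "file_path"])
    return SyntheticDataset(
        images=images,
        manifest=manifest,
        edges=edges,
        gene_archetypes={g: tuple(int(k) for k in v) for g, v in assign.items()},
        archetypes=archetypes,
        missing_genes=missing,
        config=cfg,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    """Write PNGs, manifest.tsv, edges.tsv, archetypes.json and summary.json."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for img, fname in zip(dataset.images, dataset.manifest["file_path"]):
        arr = np.round(img.pixels * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(img_dir / fname)
    dataset.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(dataset.edges, columns=["tf", "target"]).to_csv(
        out / "edges.tsv", sep="\t", index=False
    )
    (out / "archetypes.json").write_text(
        json.dumps({g: list(v) for g, v in dataset.gene_archetypes.items()}, indent=0)
    )
    cfg = asdict(dataset.config)
    cfg["images_per_orientation"] = list(cfg["images_per_orientation"])
    cfg["orientations"] = list(cfg["orientations"])
    summary = {
        "n_genes": dataset.config.n_genes,
        "n_edges": len(dataset.edges),
        "density": dataset.density,
        "missing_genes": dataset.missing_genes,
        "config": cfg,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
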