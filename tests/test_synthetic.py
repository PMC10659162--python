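"""Generator contracts: determinism, planted signal, rendering conventions."""

import numpy as np
import pytest

from miggri.data import IMAGE_HEIGHT, IMAGE_WIDTH
from miggri.synthetic import (
    PatternArchetype,
    SimulationConfig,
    embryo_canvas,
    embryo_mask,
    generate_dataset,
    render_image,
    write_dataset,
)


def small_cfg(**kw):
    base = dict(n_genes=30, n_tfs=8, n_edges=40, n_archetypes=8,
                noise_sd=0.02, jitter_px=1, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


def arch(centers, widths, intensity=0.7, aid=0):
    return PatternArchetype(aid, tuple(centers), tuple(widths), intensity)


class TestRenderImage:
    def test_deterministic_without_noise_or_jitter(self):
        a = arch([(60.0, 100.0)], [15.0])
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(1)
        im1 = render_image([a], "L", noise_sd=0.0, jitter_px=0, rng=rng1)
        im2 = render_image([a], "L", noise_sd=0.0, jitter_px=0, rng=rng2)
        np.testing.assert_array_equal(im1, im2)
        assert im1.shape == (IMAGE_HEIGHT, IMAGE_WIDTH)
        assert im1.min() >= 0.0 and im1.max() <= 1.0

    def test_zero_intensity_gives_plain_embryo_canvas(self):
        a = arch([(60.0, 100.0)], [15.0], intensity=0.0)
        im = render_image([a], "L", 0.0, 0, np.random.default_rng(0))
        np.testing.assert_array_equal(im, embryo_canvas())

    def test_empty_archetype_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            render_image([], "L", 0.0, 0, np.random.default_rng(0))

    def test_minimum_lies_near_a_blob_center(self):
        # two disjoint blobs; the darkest pixel must sit within one blob radius
        a1 = arch([(40.0, 80.0)], [12.0], intensity=0.8, aid=0)
        a2 = arch([(90.0, 240.0)], [10.0], intensity=0.5, aid=1)
        im = render_image([a1, a2], "L", 0.0, 0, np.random.default_rng(0))
        r, c = np.unravel_index(np.argmin(im), im.shape)
        d1 = np.hypot(r - 40, c - 80)
        d2 = np.hypot(r - 90, c - 240)
        assert min(d1, d2) <= 12.0

    def test_darker_means_higher_expression(self):
        a = arch([(60.0, 100.0)], [15.0], intensity=0.9)
        im = render_image([a], "L", 0.0, 0, np.random.default_rng(0))
        assert im[60, 100] < im[60, 300]  # blob center darker than far field

    def test_orientations_transform_the_pattern(self):
        a = arch([(30.0, 100.0)], [12.0])
        lat = render_image([a], "L", 0.0, 0, np.random.default_rng(0))
        dor = render_image([a], "D", 0.0, 0, np.random.default_rng(0))
        ven = render_image([a], "V", 0.0, 0, np.random.default_rng(0))
        # dorsal is the vertical mirror of lateral
        np.testing.assert_allclose(dor, np.flipud(lat), atol=1e-12)
        assert np.argmin(dor[:, 100]) == IMAGE_HEIGHT - 1 - 30
        # ventral adds a horizontal shift on top of the mirror
        assert np.argmin(ven[IMAGE_HEIGHT - 1 - 30]) == 108

    def test_blob_center_outside_mask_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            arch([(0.0, 0.0)], [10.0])

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            arch([(60.0, 100.0)], [0.0])


class TestEmbryoMask:
    def test_margin_and_center(self):
        m = embryo_mask()
        assert m[64, 160]
        assert not m[0, 0] and not m[64, 2] and not m[2, 160]
        # 6 px margin: just inside the semi-axis end is inside
        assert m[64, 8] and not m[64, 5]


class TestGenerateDataset:
    def test_same_seed_byte_identical_output(self, tmp_path):
        cfg = small_cfg()
        d1 = write_dataset(generate_dataset(cfg), tmp_path / "a")
        d2 = write_dataset(generate_dataset(cfg), tmp_path / "b")
        assert (d1 / "manifest.tsv").read_bytes() == (d2 / "manifest.tsv").read_bytes()
        assert (d1 / "edges.tsv").read_bytes() == (d2 / "edges.tsv").read_bytes()
        for f in sorted((d1 / "images").iterdir()):
            assert f.read_bytes() == (d2 / "images" / f.name).read_bytes()

    def test_missing_fraction_is_exact(self):
        ds = generate_dataset(small_cfg(n_genes=30, missing_gene_frac=0.1))
        assert len(ds.missing_genes) == 3
        with_rows = set(ds.manifest["gene_id"])
        assert all(g not in with_rows for g in ds.missing_genes)

    def test_edge_bound_rejected(self):
        with pytest.raises(ValueError, match="bipartite bound"):
            SimulationConfig(n_genes=10, n_tfs=2, n_edges=30).validate()

    def test_bad_image_dims_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(image_height=-5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(image_height=64.5).validate()  # type: ignore[arg-type]

    def test_density_matches_formula(self, small_dataset):
        n, e = 40, len(small_dataset.edges)
        assert small_dataset.density == pytest.approx(2 * e / (n * (n - 1)))

    def test_interacting_pairs_correlate_more_than_random(self):
        """Planted signal: lateral images of linked pairs out-correlate
        1,000 random non-interacting pairs on average."""
        ds = generate_dataset(SimulationConfig(
            n_genes=60, n_tfs=15, n_edges=120, pattern_share_prob=0.9,
            noise_sd=0.05, seed=7,
        ))
        sets = ds.image_sets()
        lat = {g: s.by_orientation["L"][0].pixels.ravel()
               for g, s in sets.items() if s.by_orientation["L"]}
        corr = lambda a, b: np.corrcoef(lat[a], lat[b])[0, 1]
        inter = np.mean([corr(a, b) for a, b in ds.edges])
        known = set(map(frozenset, ds.edges))
        rng = np.random.default_rng(0)
        genes = sorted(lat)
        non = []
        while len(non) < 1000:
            a, b = rng.choice(genes, 2, replace=False)
            if frozenset((a, b)) not in known:
                non.append(corr(a, b))
        assert inter > np.mean(non)

    def test_full_sharing_no_noise_beats_every_disjoint_pair(self):
        """At share=1, noise=0 each linked pair's correlation exceeds every
        archetype-disjoint pair's (exhaustively, tiny n)."""
        ds = generate_dataset(SimulationConfig(
            n_genes=20, n_tfs=5, n_edges=25, n_archetypes=12,
            pattern_share_prob=1.0, noise_sd=0.0, jitter_px=0, seed=3,
        ))
        sets = ds.image_sets()
        lat = {g: s.by_orientation["L"][0].pixels.ravel() for g, s in sets.items()}
        corr = lambda a, b: np.corrcoef(lat[a], lat[b])[0, 1]
        linked = min(corr(a, b) for a, b in ds.edges)
        arch = ds.gene_archetypes
        genes = sorted(arch)
        disjoint = [
            corr(a, b)
            for i, a in enumerate(genes) for b in genes[i + 1:]
            if not set(arch[a]) & set(arch[b])
        ]
        assert disjoint, "fixture must contain archetype-disjoint pairs"
        assert linked > max(disjoint)

    def test_noise_cannot_widen_the_correlation_gap(self):
        """The interacting-vs-random correlation gap is non-increasing in
        noise (checked across three noise levels, fixed seed)."""
        gaps = []
        for sd in (0.0, 0.15, 0.45):
            ds = generate_dataset(SimulationConfig(
                n_genes=40, n_tfs=10, n_edges=80, pattern_share_prob=0.9,
                noise_sd=sd, jitter_px=0, seed=9,
            ))
            sets = ds.image_sets()
            lat = {g: s.by_orientation["L"][0].pixels.ravel() for g, s in sets.items()}
            corr = lambda a, b: np.corrcoef(lat[a], lat[b])[0, 1]
            inter = np.mean([corr(a, b) for a, b in ds.edges])
            known = set(map(frozenset, ds.edges))
            rng = np.random.default_rng(1)
            genes = sorted(lat)
            non = []
            while len(non) < 400:
                a, b = rng.choice(genes, 2, replace=False)
                if frozenset((a, b)) not in known:
                    non.append(corr(a, b))
            gaps.append(inter - np.mean(non))
        tol = 0.02  # Monte-Carlo slack
        assert gaps[1] <= gaps[0] + tol and gaps[2] <= gaps[1] + tol

    def test_manifest_rows_match_written_files(self, tmp_path, small_dataset):
        out = write_dataset(small_dataset, tmp_path / "d")
        for row in small_dataset.manifest.itertuples(index=False):
            f = out / "images" / row.file_path
            assert f.exists()
        from PIL import Image

        with Image.open(out / "images" / small_dataset.manifest["file_path"].iloc[0]) as im:
            assert im.size == (IMAGE_WIDTH, IMAGE_HEIGHT)
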