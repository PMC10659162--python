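"""Contrastive stage: loss closed forms, pair construction, encoder training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from miggri.data import ExpressionImage
from miggri.stage1 import (
    EncoderConfig,
    Encoder,
    ImagePair,
    build_pairs,
    contrastive_loss,
    embed_image_sets,
    load_encoder,
    save_encoder,
    train_encoder,
)


def fake_image(gene, orientation, value=0.5):
    return ExpressionImage(gene, orientation, "13-16",
                           np.full((128, 320), value))


class TestContrastiveLoss:
    def test_closed_forms(self):
        x = np.array([1.0, 0.0])
        y2 = np.array([1.0, 2.0])  # distance 2 from x
        assert contrastive_loss(x, x, 1, m=1.0) == 0.0
        assert contrastive_loss(x, y2, 0, m=1.0) == 0.0  # hinge inactive
        assert contrastive_loss(x, x, 0, m=1.0) == pytest.approx(0.5)
        assert contrastive_loss(x, y2, 1, m=1.0) == pytest.approx(2.0)

    def test_hinge_continuity_at_margin(self):
        m = 1.0
        for eps in (1e-6, -1e-6):
            d = m + eps
            val = contrastive_loss(np.array([0.0]), np.array([d]), 0, m)
            assert val == pytest.approx(0.0, abs=1e-11)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.lists(st.floats(-5, 5), min_size=3, max_size=3),
        st.integers(0, 1),
        st.floats(0.1, 3.0),
    )
    def test_symmetric_and_nonnegative(self, xa, xb, y, m):
        a, b = np.array(xa), np.array(xb)
        l1 = contrastive_loss(a, b, y, m)
        assert l1 >= 0.0
        assert l1 == contrastive_loss(b, a, y, m)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            contrastive_loss(np.zeros(2), np.zeros(3), 1, 1.0)


class TestImagePair:
    def test_orientation_constraint(self):
        with pytest.raises(ValueError, match="orientation"):
            ImagePair(fake_image("a", "L"), fake_image("b", "D"), 1)

    def test_same_gene_rejected(self):
        with pytest.raises(ValueError, match="never paired"):
            ImagePair(fake_image("a", "L"), fake_image("a", "L"), 1)


class TestBuildPairs:
    def test_cartesian_product_and_constraints(self, small_dataset, small_split):
        sets = small_dataset.image_sets()
        pairs = build_pairs(small_split, sets, per_pair_cap=100, seed=0)
        # pick one train-positive gene pair and count its pairs by hand
        ga, gb = small_split.train_pos[0]
        expected = sum(
            len(sets[ga].by_orientation[o]) * len(sets[gb].by_orientation[o])
            for o in ("L", "D", "V")
        )
        got = [
            p for p in pairs
            if {p.img_a.gene_id, p.img_b.gene_id} == {ga, gb} and p.label == 1
        ]
        assert len(got) == expected
        assert all(p.img_a.orientation == p.img_b.orientation for p in pairs)

    def test_cap_subsamples_reproducibly(self):
        imgs_a = [fake_image("a", "L", v) for v in (0.1, 0.2)]
        imgs_b = [fake_image("b", "L", v) for v in (0.3, 0.4, 0.5)]
        from miggri.data import GeneImageSet, SplitSpec

        sets = {
            "a": GeneImageSet("a", {"L": imgs_a, "D": [], "V": []}),
            "b": GeneImageSet("b", {"L": imgs_b, "D": [], "V": []}),
        }
        split = SplitSpec([("a", "b")], [], [("x", "y")], [], [], [], seed=0)
        full = build_pairs(split, sets, per_pair_cap=10, seed=1)
        assert len(full) == 6
        capped = build_pairs(split, sets, per_pair_cap=4, seed=1)
        assert len(capped) == 4
        again = build_pairs(split, sets, per_pair_cap=4, seed=1)
        assert [(id(p.img_a), id(p.img_b)) for p in capped] == [
            (id(p.img_a), id(p.img_b)) for p in again
        ]

    def test_no_shared_orientation_gives_zero_pairs(self):
        from miggri.data import GeneImageSet, SplitSpec

        sets = {
            "a": GeneImageSet("a", {"L": [fake_image("a", "L")], "D": [], "V": []}),
            "b": GeneImageSet("b", {"L": [], "D": [fake_image("b", "D")], "V": []}),
        }
        split = SplitSpec([("a", "b")], [], [("x", "y")], [], [], [], seed=0)
        assert build_pairs(split, sets, seed=0) == []


class TestEncoderTraining:
    def test_weight_sharing_left_right_identical(self, small_embeddings):
        encoder, _, _ = small_embeddings
        img = np.random.default_rng(0).uniform(size=(1, 128, 320))
        np.testing.assert_array_equal(encoder.embed(img), encoder.embed(img))

    def test_training_separates_interacting_pairs(self, small_dataset, small_split,
                                                  small_embeddings):
        """After contrastive training, interacting-pair images sit closer in
        embedding space than non-interacting ones (train objective's fixed
        point, measured on training pairs)."""
        encoder, emb, _ = small_embeddings
        sets = small_dataset.image_sets()
        pairs = build_pairs(small_split, sets, per_pair_cap=2, seed=9)
        cache = {}

        def vec(im):
            if id(im) not in cache:
                cache[id(im)] = encoder.embed(im.pixels[None])[0]
            return cache[id(im)]

        d_pos = np.mean([np.linalg.norm(vec(p.img_a) - vec(p.img_b))
                         for p in pairs if p.label == 1])
        d_neg = np.mean([np.linalg.norm(vec(p.img_a) - vec(p.img_b))
                         for p in pairs if p.label == 0])
        assert d_pos < d_neg

    def test_loss_trajectory_finite_and_logged(self, small_embeddings):
        _, _, history = small_embeddings
        assert len(history["train_loss"]) == 3
        assert all(np.isfinite(v) for v in history["train_loss"])

    def test_determinism_under_seed(self, small_dataset, small_split):
        sets = small_dataset.image_sets()
        pairs = build_pairs(small_split, sets, per_pair_cap=1, seed=3)
        cfg = EncoderConfig(backbone="small_cnn", embedding_dim=8,
                            learning_rate=1e-3, batch_size=16, epochs=1,
                            seed=21, input_downsample=8)
        e1, _ = train_encoder(pairs[:60], cfg)
        e2, _ = train_encoder(pairs[:60], cfg)
        emb1 = embed_image_sets(e1, sets)
        emb2 = embed_image_sets(e2, sets)
        np.testing.assert_array_equal(emb1.to_numpy()[:, 3:].astype(float),
                                      emb2.to_numpy()[:, 3:].astype(float))

    def test_embedding_table_one_row_per_image(self, small_dataset, small_embeddings):
        _, emb, _ = small_embeddings
        assert len(emb) == len(small_dataset.images)
        assert emb.duplicated(["gene_id", "orientation", "image_index"]).sum() == 0

    def test_checkpoint_roundtrip_bit_exact(self, small_embeddings, tmp_path):
        encoder, emb, _ = small_embeddings
        save_encoder(encoder, tmp_path / "enc.npz")
        loaded = load_encoder(tmp_path / "enc.npz")
        img = np.random.default_rng(5).uniform(size=(2, 128, 320))
        np.testing.assert_array_equal(encoder.embed(img), loaded.embed(img))

    def test_empty_pair_list_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            train_encoder([], EncoderConfig())

    def test_vgg_backbone_forward_shape(self):
        cfg = EncoderConfig(backbone="vgg16_modified", embedding_dim=16,
                            input_downsample=8)
        enc = Encoder(cfg)
        out = enc.embed(np.random.default_rng(0).uniform(size=(1, 128, 320)))
        assert out.shape == (1, 16)

    def test_presets_carry_reference_hyperparameters(self):
        eye = EncoderConfig.preset("eye")
        assert (eye.learning_rate, eye.batch_size, eye.epochs, eye.margin) == (5e-6, 16, 50, 1.0)
        meso = EncoderConfig.preset("mesoderm")
        assert (meso.batch_size, meso.epochs) == (32, 22)
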