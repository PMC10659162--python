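"""Data model contracts: loading, standardization, graph, splits."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from miggri.data import (
    GRNGraph,
    SplitSpec,
    load_dataset,
    make_splits,
    standardize_pixels,
)
from miggri.synthetic import SimulationConfig, generate_dataset, write_dataset


@pytest.fixture(scope="module")
def toy_graph():
    nodes = [f"g{i}" for i in range(30)]
    edges = [(nodes[i % 5], nodes[5 + (i * 7) % 25]) for i in range(40)]
    edges = list(dict.fromkeys(edges))  # dedupe, keep order
    return GRNGraph(nodes, edges)


class TestGRNGraph:
    def test_adjacency_symmetric_zero_diagonal(self, toy_graph):
        A = toy_graph.adjacency
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)

    def test_density_matches_hand_count(self):
        g = GRNGraph(["a", "b", "c", "d"], [("a", "b"), ("c", "d")])
        assert g.density == pytest.approx(2 * 2 / (4 * 3))  # = 1/3

    def test_tf_flag_retained(self):
        g = GRNGraph(["a", "b"], [("a", "b")])
        assert g.tf_flag[frozenset(("a", "b"))] == "a"

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            GRNGraph(["a"], [("a", "a")])


class TestMakeSplits:
    def test_sizes_for_100_edges(self):
        nodes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        edges = set()
        while len(edges) < 100:
            a, b = rng.choice(40, 2, replace=False)
            edges.add((nodes[min(a, b)], nodes[max(a, b)]))
        g = GRNGraph(nodes, sorted(edges))
        s = make_splits(g, seed=4)
        assert (len(s.test_pos), len(s.train_pos), len(s.val_pos)) == (20, 72, 8)
        assert (len(s.test_neg), len(s.train_neg), len(s.val_neg)) == (20, 72, 8)

    def test_deterministic_under_seed(self, toy_graph):
        assert make_splits(toy_graph, seed=9) == make_splits(toy_graph, seed=9)
        assert make_splits(toy_graph, seed=9) != make_splits(toy_graph, seed=10)

    def test_negatives_disjoint_from_edges_and_each_other(self, toy_graph):
        s = make_splits(toy_graph, seed=2)
        known = set(map(frozenset, toy_graph.edges))
        negs = [frozenset(p) for p in s.train_neg + s.val_neg + s.test_neg]
        assert not set(negs) & known
        assert len(set(negs)) == len(negs)

    def test_no_leakage_between_partitions(self, toy_graph):
        s = make_splits(toy_graph, seed=2)
        tr = set(map(frozenset, s.train_pos + s.train_neg + s.val_pos + s.val_neg))
        te = set(map(frozenset, s.test_pos + s.test_neg))
        assert not tr & te

    def test_too_few_edges_rejected(self):
        g = GRNGraph(["a", "b", "c", "d", "e"], [("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="at least 10"):
            make_splits(g, seed=0)

    def test_exclusion_list_respected(self, toy_graph):
        banned = [("g10", "g20"), ("g11", "g21")]
        s = make_splits(toy_graph, seed=3, exclude=banned)
        negs = set(map(frozenset, s.train_neg + s.val_neg + s.test_neg))
        assert not negs & set(map(frozenset, banned))

    def test_leak_free_guard_fires_on_bad_split(self, toy_graph):
        s = make_splits(toy_graph, seed=2)
        with pytest.raises(ValueError, match="overlap|known edge"):
            SplitSpec(
                train_pos=s.train_pos, val_pos=s.val_pos, test_pos=s.test_pos,
                train_neg=[s.test_pos[0]], val_neg=s.val_neg, test_neg=s.test_neg,
                seed=0,
            )

    def test_json_roundtrip(self, toy_graph, tmp_path):
        s = make_splits(toy_graph, seed=5)
        s.to_json(tmp_path / "s.json")
        assert SplitSpec.from_json(tmp_path / "s.json") == s


class TestStandardize:
    def test_resize_to_standard_shape(self):
        arr = np.random.default_rng(0).uniform(size=(160, 400))
        out = standardize_pixels(arr)
        assert out.shape == (128, 320)
        assert out.min() >= 0 and out.max() <= 1

    def test_uint8_rescaled(self):
        arr = np.full((128, 320), 255, dtype=np.uint8)
        assert standardize_pixels(arr).max() == pytest.approx(1.0)


class TestLoadDataset:
    @pytest.fixture(scope="class")
    def written(self, tmp_path_factory):
        cfg = SimulationConfig(n_genes=12, n_tfs=4, n_edges=15, n_archetypes=6,
                               missing_gene_frac=0.25, seed=2)
        ds = generate_dataset(cfg)
        out = write_dataset(ds, tmp_path_factory.mktemp("data"))
        return ds, out

    def test_counts_per_orientation(self, written):
        ds, out = written
        sets, graph = load_dataset(out / "manifest.tsv", out / "images", out / "edges.tsv")
        gene = ds.manifest["gene_id"].iloc[0]
        counts = ds.manifest[ds.manifest.gene_id == gene]["orientation"].value_counts()
        for o in ("L", "D", "V"):
            assert len(sets[gene].by_orientation[o]) == counts.get(o, 0)

    def test_missing_genes_present_with_empty_sets(self, written):
        ds, out = written
        sets, graph = load_dataset(out / "manifest.tsv", out / "images", out / "edges.tsv")
        in_edges = {g for e in ds.edges for g in e}
        for g in ds.missing_genes:
            if g in in_edges:
                assert g in graph.index
                assert sets[g].n_images == 0

    def test_pixels_roundtrip_through_png(self, written):
        ds, out = written
        sets, _ = load_dataset(out / "manifest.tsv", out / "images", out / "edges.tsv")
        orig = ds.images[0]
        loaded = sets[orig.gene_id].by_orientation[orig.orientation][0]
        np.testing.assert_allclose(loaded.pixels, orig.pixels, atol=1 / 255 + 1e-9)

    def test_unknown_orientation_rejected(self, written, tmp_path):
        _, out = written
        bad = pd.read_csv(out / "manifest.tsv", sep="\t")
        bad.loc[0, "orientation"] = "X"
        bad.to_csv(tmp_path / "bad.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="orientation"):
            load_dataset(tmp_path / "bad.tsv", out / "images", out / "edges.tsv")

    def test_unreadable_image_names_the_file(self, written, tmp_path):
        _, out = written
        man = pd.read_csv(out / "manifest.tsv", sep="\t")
        man.loc[0, "file_path"] = "nope.png"
        man.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        with pytest.raises(OSError, match="nope.png"):
            load_dataset(tmp_path / "m.tsv", out / "images", out / "edges.tsv")

    def test_oversized_image_standardized(self, written, tmp_path):
        _, out = written
        big = tmp_path / "big.png"
        Image.fromarray(np.full((160, 400), 128, dtype=np.uint8), mode="L").save(big)
        man = pd.DataFrame(
            [{"gene_id": "gX", "orientation": "L", "stage": "13-16", "file_path": "big.png"}]
        )
        man.to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        sets, _ = load_dataset(tmp_path / "m.tsv", tmp_path, out / "edges.tsv")
        assert sets["gX"].by_orientation["L"][0].pixels.shape == (128, 320)
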