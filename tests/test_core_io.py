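import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from habspec.core_io import (
    CommunityTable, align_inputs, filter_low_abundance, rarefy,
    read_community_table, read_tree, validate_sample_frame, write_biom,
)
from habspec.synthetic import simulate_phylogeny

from conftest import random_table


class TestReadWrite:
    def test_tsv_identity_read(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\tX\tY\ns1\t1\t2\ns2\t0\t5\ns3\t3\t0\n")
        t = read_community_table(path)
        assert t.sample_ids == ["s1", "s2", "s3"]
        assert t.otu_ids == ["X", "Y"]
        assert t.counts.tolist() == [[1, 2], [0, 5], [3, 0]]

    def test_otu_rows_autodetect(self, tmp_path, tiny_table):
        path = tmp_path / "t.tsv"
        tiny_table.write_tsv(path)  # writes #OTU ID orientation
        t = read_community_table(path)
        assert t.data.equals(tiny_table.data)

    def test_duplicate_sample_id_is_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\tX\tY\ns1\t1\t2\ns1\t0\t5\n")
        with pytest.raises(ValueError, match="s1"):
            read_community_table(path)

    def test_negative_count_names_cell(self):
        frame = pd.DataFrame([[1, -2]], index=["s1"], columns=["A", "B"])
        with pytest.raises(ValueError, match="'s1'.*'B'"):
            CommunityTable(frame)

    def test_round_trip_random_table(self, tmp_path, rng):
        t = random_table(rng, 10, 20)
        for orientation in ("otus", "samples"):
            path = tmp_path / f"{orientation}.tsv"
            t.write_tsv(path, orientation=orientation)
            back = read_community_table(path)
            assert back.data.equals(t.data)

    def test_biom_round_trip(self, tmp_path, rng):
        t = random_table(rng, 6, 12)
        path = tmp_path / "t.biom"
        write_biom(t, path)
        back = read_community_table(path)
        assert back.data.equals(t.data)


class TestReadTree:
    def test_small_tree(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);")
        tree = read_tree(path)
        assert sorted(t.name for t in tree.tips()) == ["A", "B", "C"]
        total = sum(n.length for n in tree.traverse(include_self=False))
        assert total == pytest.approx(5.0)

    def test_duplicate_tip_is_error(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,A:1):1,C:2);")
        with pytest.raises(ValueError, match="duplicate"):
            read_tree(path)

    def test_missing_length_warns_and_zeroes(self, tmp_path, caplog):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B):1,C:2);")
        with caplog.at_level("WARNING", logger="habspec"):
            tree = read_tree(path)
        assert "missing branch length" in caplog.text
        assert tree.find("B").length == 0.0

    def test_round_trip_patristic(self, tmp_path):
        tree = simulate_phylogeny(50, seed=11)
        path = tmp_path / "t.nwk"
        tree.write(str(path))
        back = read_tree(path)
        ids = sorted(t.name for t in tree.tips())
        d1 = tree.tip_tip_distances(ids).data
        d2 = back.tip_tip_distances(ids).data
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestFilter:
    def make(self, totals, n_samples=4):
        rng = np.random.default_rng(0)
        cols = {}
        for i, tot in enumerate(totals):
            split = rng.multinomial(tot, np.ones(n_samples) / n_samples)
            cols[f"OTU{i}"] = split
        frame = pd.DataFrame(cols, index=[f"s{i}" for i in range(n_samples)])
        return CommunityTable(frame)

    def test_relative_abundance_threshold(self):
        # grand total 100000; OTU with total 4 is 0.004% < 0.005%
        t = self.make([4, 49996, 50000])
        out = filter_low_abundance(t, min_rel_abund=5e-5)
        assert "OTU0" not in out.otu_ids
        assert set(out.otu_ids) == {"OTU1", "OTU2"}

    def test_singleton_removed_regardless_of_threshold(self):
        t = self.make([1, 10, 10])
        out = filter_low_abundance(t, min_rel_abund=0.0)
        assert "OTU0" not in out.otu_ids

    def test_disabled_filter_is_identity(self):
        t = self.make([1, 10, 10])
        out = filter_low_abundance(t, min_rel_abund=0.0, drop_singletons=False)
        assert out.data.equals(t.data)

    def test_idempotent(self, rng):
        t = random_table(rng, 6, 40, depth=500)
        once = filter_low_abundance(t, min_rel_abund=2e-3)
        twice = filter_low_abundance(once, min_rel_abund=2e-3)
        assert once.data.equals(twice.data)

    def test_all_removed_is_error(self):
        t = self.make([2, 3])
        with pytest.raises(ValueError):
            filter_low_abundance(t, min_rel_abund=0.9)


class TestRarefy:
    def test_sums_equal_depth(self, rng):
        t = random_table(rng, 8, 30, depth=500)
        out = rarefy(t, depth=200, seed=1)
        assert (out.data.sum(axis=1) == 200).all()

    def test_shallow_sample_dropped(self, rng):
        t = random_table(rng, 5, 10, depth=500)
        frame = t.data.copy()
        frame.iloc[0] = 0
        frame.iloc[0, 0] = 399
        t2 = CommunityTable(frame)
        out = rarefy(t2, depth=400, seed=0)
        assert t2.sample_ids[0] not in out.sample_ids
        assert len(out.sample_ids) == 4

    def test_seed_determinism(self, rng):
        t = random_table(rng, 6, 30, depth=500)
        a = rarefy(t, depth=250, seed=7)
        b = rarefy(t, depth=250, seed=7)
        c = rarefy(t, depth=250, seed=8)
        assert a.data.equals(b.data)
        assert a.sample_ids == c.sample_ids
        assert not a.data.equals(c.data)

    def test_expected_counts(self):
        # E[count_j] = depth * c_j / total, checked over 1000 seeded draws
        counts = np.array([[60, 30, 10]])
        t = CommunityTable(pd.DataFrame(counts, index=["s"], columns=list("abc")))
        draws = np.array([
            rarefy(t, depth=50, seed=s, prune_zero_otus=False).counts[0]
            for s in range(1000)])
        expected = 50 * counts[0] / counts.sum()
        # multivariate hypergeometric variance
        n_tot = counts.sum()
        var = 50 * (counts[0] / n_tot) * (1 - counts[0] / n_tot) * (n_tot - 50) / (n_tot - 1)
        se = np.sqrt(var / 1000)
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9).all()

    def test_all_shallow_is_error(self, rng):
        t = random_table(rng, 3, 5, depth=50)
        with pytest.raises(ValueError):
            rarefy(t, depth=10_000)


class TestAlign:
    def test_prune_preserves_patristic(self, rng):
        tree = simulate_phylogeny(30, seed=3)
        tips = [t.name for t in tree.tips()]
        keep = tips[:20]
        table = random_table(rng, 4, 20)
        table = CommunityTable(table.data.set_axis(keep, axis=1))
        samples = pd.DataFrame({
            "site": "x", "habitat": "sediment", "latitude": 0.0,
            "longitude": 0.0}, index=table.sample_ids)
        before = tree.tip_tip_distances(keep).data.copy()
        bundle = align_inputs(table, tree, samples)
        after = bundle.tree.tip_tip_distances(keep).data
        np.testing.assert_allclose(before, after, atol=1e-9)
        assert sorted(t.name for t in bundle.tree.tips()) == sorted(keep)

    def test_missing_otu_is_error(self, rng, example_tree):
        table = random_table(rng, 3, 4)
        samples = pd.DataFrame({"site": "x", "habitat": "sediment",
                                "latitude": 0.0, "longitude": 0.0},
                               index=table.sample_ids)
        with pytest.raises(ValueError, match="missing from tree"):
            align_inputs(table, example_tree, samples)

    def test_matched_inputs_unchanged(self, rng, example_tree):
        table = random_table(rng, 3, 3)
        table = CommunityTable(table.data.set_axis(["A", "B", "C"], axis=1))
        samples = pd.DataFrame({"site": "x", "habitat": "sediment",
                                "latitude": 0.0, "longitude": 0.0},
                               index=table.sample_ids)
        bundle = align_inputs(table, example_tree, samples)
        assert bundle.table.data.equals(table.data)
        assert bundle.samples.index.tolist() == table.sample_ids

    def test_sample_without_metadata_is_error(self, rng, example_tree):
        table = random_table(rng, 3, 3)
        table = CommunityTable(table.data.set_axis(["A", "B", "C"], axis=1))
        samples = pd.DataFrame({"site": "x", "habitat": "sediment",
                                "latitude": 0.0, "longitude": 0.0},
                               index=table.sample_ids[:2])
        with pytest.raises(ValueError, match="metadata"):
            align_inputs(table, example_tree, samples)


def test_latitude_validation():
    frame = pd.DataFrame({"site": ["x"], "habitat": ["sediment"],
                          "latitude": [95.0], "longitude": [0.0]},
                         index=["s1"])
    with pytest.raises(ValueError, match="latitude"):
        validate_sample_frame(frame)
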