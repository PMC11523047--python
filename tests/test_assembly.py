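import numpy as np
import pandas as pd
import pytest

from habspec.assembly import (
    beta_mntd, beta_nti, classify_pair, classify_processes, patristic_matrix,
    raup_crick_bray, summarize_processes,
)
from habspec.core_io import CommunityTable
from habspec.synthetic import simulate_phylogeny, simulate_under_process

from conftest import random_table


def brute_force_bmntd(counts, d, weighted=True):
    """Double-loop oracle for one pair of count vectors."""
    x, y = counts
    ix = np.flatnonzero(x)
    iy = np.flatnonzero(y)
    fx = x / x.sum() if weighted else (x > 0) / (x > 0).sum()
    fy = y / y.sum() if weighted else (y > 0) / (y > 0).sum()
    part1 = sum(fx[i] * min(d[i, j] for j in iy) for i in ix)
    part2 = sum(fy[j] * min(d[i, j] for i in ix) for j in iy)
    return 0.5 * (part1 + part2)


class TestBetaMntd:
    def test_identical_communities_zero(self, example_tree):
        t = CommunityTable(pd.DataFrame([[1, 2, 3], [1, 2, 3]],
                                        index=["x", "y"], columns=["A", "B", "C"]))
        assert beta_mntd(t, example_tree).data[0, 1] == pytest.approx(0.0)

    def test_single_taxon_pair_is_patristic_distance(self, example_tree):
        t = CommunityTable(pd.DataFrame([[5, 0, 0], [0, 0, 7]],
                                        index=["x", "y"], columns=["A", "B", "C"]))
        assert beta_mntd(t, example_tree).data[0, 1] == pytest.approx(4.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(17)
        for seed in range(10):
            tree = simulate_phylogeny(rng.integers(5, 20), seed=seed)
            otus = [t.name for t in tree.tips()]
            d = patristic_matrix(tree, otus)
            counts = rng.integers(0, 5, size=(4, len(otus)))
            counts[:, 0] += 1
            t = CommunityTable(pd.DataFrame(counts, columns=otus,
                                            index=[f"s{i}" for i in range(4)]))
            ours = beta_mntd(t, tree, weighted=weighted).data
            for i in range(4):
                for j in range(i + 1, 4):
                    ref = brute_force_bmntd(counts[[i, j]].astype(float), d, weighted)
                    assert ours[i, j] == pytest.approx(ref, abs=1e-12)

    def test_empty_sample_is_error(self, example_tree):
        frame = pd.DataFrame([[1, 1, 0], [0, 0, 0]], index=["x", "y"],
                             columns=["A", "B", "C"])
        t = CommunityTable.__new__(CommunityTable)
        t.data = frame
        with pytest.raises(ValueError):
            beta_mntd(t, example_tree)


class TestBetaNti:
    def test_seed_determinism(self, rng):
        tree = simulate_phylogeny(25, seed=1)
        t = random_table(rng, 5, 25)
        t = CommunityTable(t.data.set_axis([x.name for x in tree.tips()], axis=1))
        a = beta_nti(t, tree, n_null=99, seed=4)
        b = beta_nti(t, tree, n_null=99, seed=4)
        np.testing.assert_array_equal(a.nti, b.nti)

    def test_branch_length_scaling_invariance(self, rng):
        tree = simulate_phylogeny(20, seed=2)
        t = random_table(rng, 4, 20)
        t = CommunityTable(t.data.set_axis([x.name for x in tree.tips()], axis=1))
        a = beta_nti(t, tree, n_null=99, seed=7)
        scaled = tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length = (node.length or 0.0) * 3.5
        b = beta_nti(t, scaled, n_null=99, seed=7)
        np.testing.assert_allclose(a.nti, b.nti, atol=1e-9, equal_nan=True)

    def test_identical_pair_flagged_undefined(self, example_tree, caplog):
        t = CommunityTable(pd.DataFrame([[1, 2, 3], [1, 2, 3]],
                                        index=["x", "y"], columns=["A", "B", "C"]))
        with caplog.at_level("WARNING", logger="habspec"):
            res = beta_nti(t, example_tree, n_null=99, seed=0)
        assert np.isnan(res.nti[0, 1])
        assert "undefined" in caplog.text

    def test_shallow_turnover_strongly_negative(self):
        # communities sharing most taxa whose sole unshared taxa are an
        # abundant sister-tip cherry: observed turnover is phylogenetically
        # far shallower than the taxa-shuffle null
        tree = simulate_phylogeny(40, seed=9)
        otus = [t.name for t in tree.tips()]
        d = patristic_matrix(tree, otus)
        off = d + np.eye(40) * d.max()
        cherries, used = [], set()
        for k in np.argsort(off, axis=None):
            i, j = np.unravel_index(k, off.shape)
            if i < j and not {i, j} & used:
                cherries.append((i, j))
                used |= {i, j}
            if len(cherries) == 3:
                break
        rng = np.random.default_rng(0)
        shared = rng.choice([k for k in range(40) if k not in used], 15,
                            replace=False)
        x = np.zeros(40, dtype=int)
        x[shared] = 2
        y = x.copy()
        for i, j in cherries:
            x[i] = 30  # abundant, only in x
            y[j] = 30  # its sister, only in y
        t = CommunityTable(pd.DataFrame([x, y], index=["x", "y"], columns=otus))
        res = beta_nti(t, tree, n_null=299, seed=3)
        assert res.nti[0, 1] < -2


class TestRaupCrick:
    def test_rc_bounded(self, rng):
        t = random_table(rng, 6, 30, depth=300)
        rc = raup_crick_bray(t, n_null=99, seed=0)
        iu = np.triu_indices(6, 1)
        assert np.abs(rc.rc[iu]).max() <= 1.0

    def test_identical_samples_near_minus_one(self, rng):
        # two identical samples in a diverse metacommunity of distinct samples
        t = random_table(rng, 10, 60, depth=500)
        frame = t.data.copy()
        frame.iloc[1] = frame.iloc[0]
        t = CommunityTable(frame)
        rc = raup_crick_bray(t, n_null=999, seed=1)
        assert rc.rc[0, 1] < -0.9

    def test_disjoint_samples_near_plus_one(self, rng):
        t = random_table(rng, 10, 60, depth=500)
        frame = t.data.copy()
        frame.iloc[0, :30] = frame.iloc[0, 30:].to_numpy()
        frame.iloc[0, 30:] = 0
        frame.iloc[1, :30] = 0
        t = CommunityTable(frame)
        rc = raup_crick_bray(t, n_null=999, seed=2)
        assert rc.rc[0, 1] > 0.9

    def test_pairs_mode_matches_full_matrix(self, rng):
        t = random_table(rng, 5, 20, depth=200)
        pairs = [("s0", "s3"), ("s1", "s4")]
        full = raup_crick_bray(t, n_null=199, seed=5)
        sub = raup_crick_bray(t, n_null=199, seed=5, pairs=pairs)
        # same null machinery, same seeds: values agree statistically
        for a, b in pairs:
            i, j = t.sample_ids.index(a), t.sample_ids.index(b)
            assert abs(full.rc[i, j] - sub.rc[i, j]) < 0.25

    def test_zero_nulls_is_error(self, rng):
        with pytest.raises(ValueError):
            raup_crick_bray(random_table(rng, 3, 5), n_null=0)


class TestClassification:
    @pytest.mark.parametrize("bnti,rc,expected", [
        (2.5, None, "variable_selection"),
        (-2.5, None, "homogeneous_selection"),
        (0.5, 0.97, "dispersal_limitation"),
        (0.5, -0.97, "homogenizing_dispersal"),
        (1.0, 0.0, "drift"),
        (2.0, 0.0, "drift"),       # boundary goes to the stochastic side
        (-2.0, 0.96, "dispersal_limitation"),
        (1.5, 0.95, "drift"),      # RC boundary inclusive of drift
    ])
    def test_threshold_rules(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_missing_rc_is_error(self):
        with pytest.raises(ValueError):
            classify_pair(1.0, None)

    def test_summary_combinatorics(self):
        # 3 sites x 4 samples: 18 intra pairs, 48 inter pairs
        ids = [f"s{i}" for i in range(12)]
        samples = pd.DataFrame({
            "site": np.repeat(["a", "b", "c"], 4),
            "habitat": "sediment"}, index=ids)
        rows = []
        for i in range(12):
            for j in range(i + 1, 12):
                rows.append({"sample_a": ids[i], "sample_b": ids[j],
                             "bnti": 0.0, "rc_bray": 0.0, "process": "drift"})
        summary = summarize_processes(pd.DataFrame(rows), samples)
        intra = summary[summary["scale"] == "intra_site"].iloc[0]
        inter = summary[summary["scale"] == "inter_site"].iloc[0]
        assert intra["n_pairs"] == 18
        assert inter["n_pairs"] == 48
        assert intra["drift"] == pytest.approx(1.0)
        labels = ["variable_selection", "homogeneous_selection",
                  "homogenizing_dispersal", "dispersal_limitation", "drift"]
        assert summary[labels].sum(axis=1).round(9).eq(1.0).all()

    def test_cross_habitat_pairs_rejected(self):
        samples = pd.DataFrame({"site": ["a", "a"], "habitat": ["sediment", "gut_tissue"]},
                               index=["s1", "s2"])
        cls = pd.DataFrame([{"sample_a": "s1", "sample_b": "s2", "bnti": 0.0,
                             "rc_bray": 0.0, "process": "drift"}])
        with pytest.raises(ValueError, match="cross-habitat"):
            summarize_processes(cls, samples)

    def test_end_to_end_classification(self):
        table, tree, pairs = simulate_under_process("dispersal_limitation", 8, seed=3)
        bn = beta_nti(table, tree, n_null=99, seed=1)
        rc = raup_crick_bray(table, n_null=99, seed=2)
        cls = classify_processes(bn, rc)
        designated = cls.set_index(["sample_a", "sample_b"]).loc[pairs, "process"]
        assert (designated == "dispersal_limitation").mean() > 0.5
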