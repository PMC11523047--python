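import numpy as np
import pandas as pd
import pytest
import skbio.stats.distance as sksd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from habspec.beta import (
    bray_curtis, jaccard_binary, pairwise_permanova, pcoa, permanova,
    permdisp, unweighted_unifrac,
)
from habspec.core_io import CommunityTable
from habspec.synthetic import simulate_phylogeny

from conftest import random_table


def table_from(rows, otus, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return CommunityTable(pd.DataFrame(rows, index=ids, columns=otus))


class TestDissimilarities:
    def test_bray_hand_case(self):
        t = table_from([[1, 2, 3], [3, 2, 1]], ["a", "b", "c"])
        assert bray_curtis(t).data[0, 1] == pytest.approx(1 / 3)

    def test_bray_identical_and_disjoint(self):
        t = table_from([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]], list("abcd"))
        d = bray_curtis(t).data
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(1.0)

    def test_jaccard_hand_case(self):
        t = table_from([[1, 1, 0], [0, 1, 1]], ["a", "b", "c"])
        assert jaccard_binary(t).data[0, 1] == pytest.approx(2 / 3)

    def test_presence_only_invariance(self, rng):
        t = random_table(rng, 5, 12)
        scaled = CommunityTable(t.data * 13)
        np.testing.assert_allclose(jaccard_binary(t).data, jaccard_binary(scaled).data)

    def test_range_and_symmetry(self, rng):
        t = random_table(rng, 8, 15)
        for dm in (bray_curtis(t), jaccard_binary(t)):
            assert dm.data.max() <= 1 + 1e-12
            assert dm.data.min() >= 0
            np.testing.assert_allclose(dm.data, dm.data.T, atol=1e-12)

    def test_all_zero_sample_is_error(self):
        frame = pd.DataFrame([[1, 2], [0, 0]], index=["a", "b"], columns=["x", "y"])
        t = CommunityTable.__new__(CommunityTable)
        t.data = frame
        with pytest.raises(ValueError):
            bray_curtis(t)


def brute_force_unifrac(table, tree):
    """Branch-by-branch tally oracle."""
    tips = {t.name for t in tree.tips()}
    otus = np.array(table.otu_ids)
    n = len(table.sample_ids)
    out = np.zeros((n, n))
    presence = [set(otus[row > 0]) & tips for row in table.counts]
    branches = []
    for node in tree.traverse(include_self=False):
        under = {t.name for t in node.tips()} or {node.name}
        branches.append((node.length or 0.0, under))
    for i in range(n):
        for j in range(i + 1, n):
            unique = union = 0.0
            for length, under in branches:
                in_a = bool(under & presence[i])
                in_b = bool(under & presence[j])
                if in_a or in_b:
                    union += length
                if in_a != in_b:
                    unique += length
            out[i, j] = out[j, i] = unique / union if union else 0.0
    return out


class TestUnifrac:
    def test_identical_sets_zero(self, example_tree):
        t = table_from([[1, 1, 0], [2, 9, 0]], ["A", "B", "C"])
        assert unweighted_unifrac(t, example_tree).data[0, 1] == pytest.approx(0.0)

    def test_star_like_disjoint_singletons(self):
        # patristically a star with unit tip branches (zero-length internals
        # keep the root bifurcating): unique = t1+t2 = 2, union = 2
        import io
        from skbio import TreeNode
        star = TreeNode.read(io.StringIO("((t1:1,t2:1):0,(t3:1,t4:1):0);"))
        t = table_from([[1, 0, 0, 0], [0, 1, 0, 0]], ["t1", "t2", "t3", "t4"])
        assert unweighted_unifrac(t, star).data[0, 1] == pytest.approx(1.0)

    def test_hand_enumerated_case(self, example_tree):
        # {A,B} vs {A,C}: unique B(1)+C(2)=3, union A+B+stem+C=5
        t = table_from([[1, 1, 0], [1, 0, 1]], ["A", "B", "C"])
        assert unweighted_unifrac(t, example_tree).data[0, 1] == pytest.approx(0.6)

    def test_matches_brute_force_oracle(self, rng):
        for seed in range(5):
            tree = simulate_phylogeny(15, seed=seed)
            otus = [t.name for t in tree.tips()]
            counts = (rng.random((6, 15)) < 0.4).astype(int)
            counts[:, 0] = 1
            t = table_from(counts, otus)
            ours = unweighted_unifrac(t, tree).data
            oracle = brute_force_unifrac(t, tree)
            np.testing.assert_allclose(ours, oracle, atol=1e-12)


class TestPcoa:
    def test_collinear_points_recovered(self):
        d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        x = res.coordinates.iloc[:, 0].to_numpy()
        gaps = np.diff(np.sort(x))
        np.testing.assert_allclose(sorted(gaps), [1, 2], atol=1e-9)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_input_nonnegative_eigenvalues(self, rng):
        pts = rng.normal(size=(8, 3))
        res = pcoa(DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(8)]))
        assert res.eigenvalues.min() > -1e-9

    def test_duplicate_points_identical_coordinates(self):
        d = np.array([[0, 0, 2], [0, 0, 2], [2, 2, 0]], float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        np.testing.assert_allclose(res.coordinates.iloc[0], res.coordinates.iloc[1],
                                   atol=1e-9)


class TestPermanova:
    def test_degenerate_clusters(self):
        d = np.zeros((8, 8))
        d[:4, 4:] = d[4:, :4] = 1.0
        dm = DistanceMatrix(d, ids=[str(i) for i in range(8)])
        groups = np.array([0] * 4 + [1] * 4)
        res = permanova(dm, groups, n_perm=199, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.pvalue <= 0.05

    def test_relabel_invariance(self, rng):
        pts = rng.normal(size=(16, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(16)])
        g1 = np.array(["a"] * 8 + ["b"] * 8)
        g2 = np.array(["b"] * 8 + ["a"] * 8)
        r1 = permanova(dm, g1, n_perm=99, seed=3)
        r2 = permanova(dm, g2, n_perm=99, seed=3)
        assert r1.r2 == pytest.approx(r2.r2, abs=1e-12)
        assert r1.pvalue == r2.pvalue

    def test_statistic_matches_skbio(self, rng):
        pts = rng.normal(size=(18, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(18)])
        groups = np.repeat(["a", "b", "c"], 6)
        ours = permanova(dm, groups, n_perm=99, seed=0)
        ref = sksd.permanova(dm, list(groups), permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 500
        for s in range(n_sim):
            pts = rng.normal(size=(16, 4))
            dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(16)])
            res = permanova(dm, np.array([0] * 8 + [1] * 8), n_perm=99, seed=s)
            rejections += res.pvalue <= 0.05
        assert abs(rejections / n_sim - 0.05) < 0.025

    def test_single_group_is_error(self, rng):
        pts = rng.normal(size=(6, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(6)])
        with pytest.raises(ValueError):
            permanova(dm, np.zeros(6, dtype=int))


class TestPairwisePermanova:
    def test_three_groups_three_tests(self, rng):
        pts = rng.normal(size=(18, 3))
        pts[6:12] += 4
        pts[12:] += 8
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(18)])
        groups = np.repeat(["a", "b", "c"], 6)
        out = pairwise_permanova(dm, groups, n_perm=99, seed=0)
        assert len(out) == 3
        assert (out["p_holm"] >= out["p_raw"] - 1e-12).all()


class TestPermdisp:
    def test_identical_points_zero_dispersion(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = d[3:, :3] = 1.0
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        res = permdisp(dm, np.array([0] * 3 + [1] * 3), n_perm=99, seed=0)
        assert res.group_means.max() == pytest.approx(0.0, abs=1e-9)

    def test_scaled_group_detected(self, rng):
        pts = rng.normal(size=(40, 3))
        pts[20:] *= 5
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(40)])
        res = permdisp(dm, np.array([0] * 20 + [1] * 20), n_perm=199, seed=1)
        assert res.pvalue <= 0.05
        assert res.group_means[1] > res.group_means[0]

    def test_equal_dispersion_not_rejected(self, rng):
        hits = 0
        for s in range(20):
            pts = rng.normal(size=(30, 3))
            dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(30)])
            res = permdisp(dm, np.array([0] * 15 + [1] * 15), n_perm=99, seed=s)
            hits += res.pvalue <= 0.05
        assert hits <= 3
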