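"""Community distances, ordination, PERMANOVA and clustering."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
import skbio.stats.distance as sksd

from biomevol.community import (
    kmedoid_gap,
    pairwise_permanova,
    pam,
    pcoa,
    permanova,
    weighted_unifrac,
)
from biomevol.simulate import BDParams, simulate_bd_tree
from biomevol.tables import OccupancyTable
from biomevol.trees import read_newick


def _table(counts, biomes):
    idx = [f"s{i}" for i in range(counts.shape[0])]
    return OccupancyTable(
        pd.DataFrame(counts, index=idx, columns=[f"t{j+1}" for j in range(counts.shape[1])]),
        pd.Series(biomes, index=idx),
    )


class TestWeightedUnifrac:
    def test_identical_profiles_have_zero_distance(self):
        tree = read_newick("(t1:1,t2:1):0;")
        tab = _table(np.array([[3, 1], [6, 2]]), ["a", "a"])
        dm = weighted_unifrac(tab, tree)
        assert dm["s0", "s1"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_two_tip_hand_value(self):
        tree = read_newick("(t1:1,t2:1):0;")
        tab = _table(np.array([[5, 0], [0, 3]]), ["a", "b"])
        assert weighted_unifrac(tab, tree, normalized=False)["s0", "s1"] == pytest.approx(2.0)
        assert weighted_unifrac(tab, tree, normalized=True)["s0", "s1"] == pytest.approx(1.0)

    def test_matches_scikit_bio_on_integer_counts(self):
        tree = simulate_bd_tree(BDParams(1.0, 0.0, n=20), seed=3)
        tree.root.length = 0.0  # skbio counts a root stem in its normalization
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, (6, 20))
        counts[:, 0] += 1
        tab = _table(counts, ["a"] * 3 + ["b"] * 3)
        tab.counts.columns = tree.tip_labels
        sk_tree = TreeNode.read(io.StringIO(tree.to_newick()))
        for normalized in (False, True):
            mine = weighted_unifrac(tab, tree, normalized=normalized)
            ref = beta_diversity(
                "weighted_unifrac", counts, ids=list(tab.counts.index),
                taxa=list(tab.counts.columns), tree=sk_tree, normalized=normalized,
            )
            assert np.abs(mine.data - ref.data).max() < 1e-10

    def test_normalized_is_a_metric_on_random_tables(self):
        tree = simulate_bd_tree(BDParams(1.0, 0.0, n=15), seed=5)
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 20, (8, 15)) + (rng.random((8, 15)) < 0.2)
        counts[:, 0] += 1
        tab = _table(counts, ["a"] * 8)
        tab.counts.columns = tree.tip_labels
        dm = weighted_unifrac(tab, tree, normalized=True)
        D = dm.data
        assert np.abs(D - D.T).max() < 1e-12
        assert (D >= -1e-12).all() and (D <= 1 + 1e-12).all()
        n = D.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-10

    def test_missing_taxa_listed(self):
        tree = read_newick("(t1:1,t2:1):0;")
        tab = _table(np.array([[1, 1, 1]]), ["a"])
        with pytest.raises(ValueError, match="t3"):
            weighted_unifrac(tab, tree)


class TestPCoA:
    def test_collinear_points_give_one_axis(self):
        D = DistanceMatrix(np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])),
                           ids=list("abc"))
        res = pcoa(D)
        assert res.coordinates.shape[1] == 1
        rec = squareform(pdist(res.coordinates.values))
        assert np.abs(rec - D.data).max() < 1e-12

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        D = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(12)])
        res = pcoa(D)
        rec = squareform(pdist(res.coordinates.values))
        assert np.abs(rec - D.data).max() < 1e-8

    def test_non_euclidean_negative_axes_dropped(self):
        # violates the triangle inequality: d(a,c) > d(a,b) + d(b,c)
        D = np.array(
            [[0, 1, 3.5, 1], [1, 0, 1, 1], [3.5, 1, 0, 1], [1, 1, 1, 0]], dtype=float
        )
        res = pcoa(DistanceMatrix(D, ids=list("abcd")))
        assert res.n_dropped >= 1
        assert (res.eigenvalues > 0).all()

    def test_degenerate_all_zero_distances(self):
        with pytest.raises(ValueError, match="positive eigenvalue"):
            pcoa(DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))


@pytest.fixture(scope="module")
def separated():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(c, 0.05, (5, 2)) for c in ([0, 0], [50, 0], [0, 50])])
    return DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(15)])


SEP_GROUPS = ["a"] * 5 + ["b"] * 5 + ["c"] * 5


class TestPermanova:
    def test_perfect_separation_attains_minimal_p(self, separated):
        res = permanova(separated, SEP_GROUPS, n_perm=999, seed=0)
        assert res["p"] == pytest.approx(1 / 1000)
        assert res["R2"] > 0.99

    def test_pseudo_f_matches_hand_partition(self):
        """6-sample fixture: for Euclidean distances the Gower partition
        equals the coordinate sums of squares, computed here independently."""
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        groups = ["a", "a", "a", "b", "b", "b"]
        ss_total = ((X - X.mean()) ** 2).sum()
        ss_within = sum(((X[i:i + 3] - X[i:i + 3].mean()) ** 2).sum() for i in (0, 3))
        f_hand = ((ss_total - ss_within) / 1) / (ss_within / 4)
        D = DistanceMatrix(squareform(pdist(X)), ids=list("pqrstu"))
        res = permanova(D, groups, n_perm=99, seed=0)
        assert res["pseudo_F"] == pytest.approx(f_hand, rel=1e-12)
        assert res["pseudo_F"] == pytest.approx(150.0)  # frozen hand value
        assert res["R2"] == pytest.approx((ss_total - ss_within) / ss_total, rel=1e-12)

    def test_pseudo_f_matches_scikit_bio(self, separated):
        res = permanova(separated, SEP_GROUPS, n_perm=99, seed=0)
        ref = sksd.permanova(separated, grouping=SEP_GROUPS, permutations=99)
        assert res["pseudo_F"] == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_null_p_values_are_uniform(self):
        """Groups drawn from one distribution: p-values over replicate
        datasets are ~Uniform(0,1)."""
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(10_000 + rep)
            X = rng.normal(size=(12, 2))
            D = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(12)])
            pvals.append(permanova(D, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=rep)["p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_single_group_rejected(self, separated):
        with pytest.raises(ValueError):
            permanova(separated, ["a"] * 15, n_perm=9, seed=0)


class TestPairwise:
    def test_bh_adjustment_hand_example(self):
        # step-up rule on (0.01, 0.02, 0.03, 0.04), m=4 -> all 0.04
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_single_pair_unadjusted(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(5, 1, (5, 2))])
        D = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(10)])
        out = pairwise_permanova(D, ["a"] * 5 + ["b"] * 5, n_perm=99, seed=0)
        assert len(out) == 1
        assert out.loc[0, "p_adjusted"] == out.loc[0, "p"]

    def test_identical_groups_seldom_significant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(18, 2))
        D = DistanceMatrix(squareform(pdist(X)), ids=[str(i) for i in range(18)])
        out = pairwise_permanova(D, ["a", "b", "c"] * 6, n_perm=199, seed=0)
        assert (out["p_adjusted"] > 0.05).all()


class TestClustering:
    def test_pam_objective_never_increases(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        D = squareform(pdist(X))
        medoids, assign = pam(D, 4)
        # swapping any medoid for any non-medoid cannot improve the objective
        base = D[np.arange(30), np.asarray(medoids)[np.argmin(D[:, medoids], axis=1)]].sum()
        for mi in range(4):
            for h in range(30):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                cost = D[:, trial].min(axis=1).sum()
                assert cost >= base - 1e-9

    def test_gap_selects_three_separated_blobs(self):
        rng = np.random.default_rng(4)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([rng.normal(c, 0.1, (20, 2)) for c in centers])
        res = kmedoid_gap(X, range(1, 6), B=50, seed=1)
        assert res.k == 3
        # clusters coincide with the generating blobs
        lab = res.assignments
        for i in range(3):
            assert len(np.unique(lab[20 * i:20 * (i + 1)])) == 1

    def test_single_blob_selects_k1(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (50, 2))
        res = kmedoid_gap(X, range(1, 6), B=50, seed=1)
        assert res.k == 1

    def test_k1_dispersion_is_total(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 2))
        res = kmedoid_gap(X, [1, 2], B=10, seed=0)
        d2 = squareform(pdist(X)) ** 2
        total = d2.sum() / (2 * 15)
        row = res.gap_curve.set_index("k").loc[1]
        assert np.exp(row["logW"]) == pytest.approx(total, rel=1e-9)

    def test_b_too_small_rejected(self):
        with pytest.raises(ValueError, match="B >= 10"):
            kmedoid_gap(np.random.default_rng(0).normal(size=(10, 2)), [1, 2], B=5)
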