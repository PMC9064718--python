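"""Validity indices: worked examples, invariances, chance levels, and
agreement with independent reference implementations."""

import numpy as np
import pytest
import sklearn.metrics as skm

from trajensemble.distances import DistanceMatrix
from trajensemble.evaluation import (
    ContingencyTable,
    adjusted_rand,
    chi_square,
    cross_tabulate,
    dunn_index,
    fowlkes_mallows,
    purity,
    silhouette_avg,
)


def pair_counting_ari(a, b):
    """Independent ARI oracle: enumerate all unordered element pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    together_a = together_b = both = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            together_a += sa
            together_b += sb
            both += sa and sb
    expected = together_a * together_b / pairs
    max_index = (together_a + together_b) / 2
    if max_index == expected:
        return 0.0
    return (both - expected) / (max_index - expected)


class TestAdjustedRand:
    def test_identical_partitions(self):
        assert adjusted_rand([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_against_singletons_is_zero(self):
        assert adjusted_rand([1, 1, 2, 2], [1, 2, 3, 4]) == 0.0

    def test_crossed_partition_matches_pair_counting(self):
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        assert adjusted_rand(a, b) == pytest.approx(pair_counting_ari(a, b))
        assert adjusted_rand(a, b) == pytest.approx(-0.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal-length"):
            adjusted_rand([1, 2], [1, 2, 3])


class TestFowlkesMallows:
    def test_identical(self):
        assert fowlkes_mallows([1, 1, 2], [1, 1, 2]) == 1.0

    def test_fully_crossed_pairs_share_nothing(self):
        # {1,2},{3,4} vs {1,3},{2,4}: no pair co-clustered in both
        assert fowlkes_mallows([1, 1, 2, 2], [1, 2, 1, 2]) == 0.0

    def test_relabeling_invariance(self, rng):
        a = rng.integers(0, 4, size=30)
        remap = {0: "d", 1: "c", 2: "b", 3: "a"}
        b = np.array([remap[x] for x in a])
        assert fowlkes_mallows(a, b) == 1.0


class TestPurity:
    def test_exact_match(self):
        assert purity([1, 2, 1], [1, 2, 1]) == 1.0

    def test_majority_overlap(self):
        assert purity([1, 1, 1, 2, 2], ["a", "a", "b", "b", "b"]) == 0.8

    def test_singletons_are_trivially_pure(self):
        assert purity([1, 2, 3, 4], ["a", "a", "b", "b"]) == 1.0


class TestReferenceAgreement:
    def test_indices_match_scikit_learn_on_100_random_pairs(self, rng):
        """ARI and Fowlkes–Mallows must agree with scikit-learn to 1e-10
        on random label pairs (including degenerate ones)."""
        for _ in range(100):
            n = int(rng.integers(5, 60))
            a = rng.integers(0, int(rng.integers(2, 6)), size=n)
            b = rng.integers(0, int(rng.integers(2, 6)), size=n)
            assert adjusted_rand(a, b) == pytest.approx(
                skm.adjusted_rand_score(a, b), abs=1e-10
            )
            assert fowlkes_mallows(a, b) == pytest.approx(
                skm.fowlkes_mallows_score(a, b), abs=1e-10
            )

    def test_silhouette_matches_scikit_learn(self, rng):
        from conftest import random_distance_matrix

        for _ in range(20):
            n = int(rng.integers(6, 20))
            d = random_distance_matrix(rng, n)
            labels = rng.integers(0, 3, size=n)
            if len(np.unique(labels)) < 2 or np.min(np.bincount(labels)) < 2:
                continue
            ours = silhouette_avg(d, labels)
            theirs = skm.silhouette_score(
                d.matrix, labels, metric="precomputed"
            )
            assert ours == pytest.approx(theirs, abs=1e-10)


class TestChanceLevels:
    def test_ari_and_fm_at_chance_for_independent_partitions(self):
        """Independent balanced 3-group partitions (n=200, 1000 reps): mean
        ARI within 3 SE of 0, mean FM within 3 SE of its analytic chance
        value sqrt(Pa*Pb) for co-membership probabilities Pa, Pb."""
        rng = np.random.default_rng(77)
        n, reps = 200, 1000
        base = np.repeat([0, 1, 2], [67, 67, 66])
        aris, fms = [], []
        for _ in range(reps):
            a = rng.permutation(base)
            b = rng.permutation(base)
            aris.append(adjusted_rand(a, b))
            fms.append(fowlkes_mallows(a, b))
        aris, fms = np.array(aris), np.array(fms)
        pairs = n * (n - 1) / 2
        co = (67 * 66 / 2) * 2 + (66 * 65 / 2)
        chance_fm = np.sqrt((co / pairs) * (co / pairs))
        assert abs(aris.mean()) < 3 * aris.std(ddof=1) / np.sqrt(reps)
        assert abs(fms.mean() - chance_fm) < 3 * fms.std(ddof=1) / np.sqrt(reps)


class TestSilhouette:
    def test_two_tight_separated_clusters(self):
        m = np.zeros((4, 4))
        m[:2, 2:] = 10.0
        m[2:, :2] = 10.0
        d = DistanceMatrix(tuple("abcd"), m)
        assert silhouette_avg(d, [1, 1, 2, 2]) == 1.0

    def test_equidistant_points_score_zero(self):
        m = np.full((4, 4), 3.0)
        np.fill_diagonal(m, 0.0)
        d = DistanceMatrix(tuple("abcd"), m)
        # every point: a = b = 3, so s = 0 regardless of the 2-way split
        assert silhouette_avg(d, [1, 1, 2, 2]) == 0.0
        assert silhouette_avg(d, [1, 2, 2, 2]) == 0.0

    def test_singleton_contributes_zero(self):
        m = np.array(
            [[0.0, 1.0, 5.0], [1.0, 0.0, 5.0], [5.0, 5.0, 0.0]]
        )
        d = DistanceMatrix(tuple("abc"), m)
        # points a,b: s = (5-1)/5 = 0.8; singleton c: 0
        assert silhouette_avg(d, [1, 1, 2]) == pytest.approx((0.8 + 0.8) / 3)

    def test_single_cluster_is_an_error(self):
        d = DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError, match="at least 2"):
            silhouette_avg(d, [1, 1])


class TestDunn:
    def test_separation_over_diameter(self):
        m = np.array(
            [
                [0.0, 1.0, 10.0, 10.0],
                [1.0, 0.0, 10.0, 10.0],
                [10.0, 10.0, 0.0, 2.0],
                [10.0, 10.0, 2.0, 0.0],
            ]
        )
        d = DistanceMatrix(tuple("abcd"), m)
        assert dunn_index(d, [1, 1, 2, 2]) == 5.0

    def test_all_singletons_is_infinite(self):
        m = np.full((3, 3), 4.0)
        np.fill_diagonal(m, 0.0)
        d = DistanceMatrix(tuple("abc"), m)
        assert dunn_index(d, [1, 2, 3]) == float("inf")

    def test_grows_with_separation(self):
        def matrix(sep):
            m = np.array(
                [
                    [0.0, 1.0, sep, sep],
                    [1.0, 0.0, sep, sep],
                    [sep, sep, 0.0, 1.0],
                    [sep, sep, 1.0, 0.0],
                ]
            )
            return DistanceMatrix(tuple("abcd"), m)

        assert dunn_index(matrix(50.0), [1, 1, 2, 2]) > dunn_index(
            matrix(5.0), [1, 1, 2, 2]
        )


class TestChiSquare:
    def test_independence_table_is_zero(self):
        t = ContingencyTable(
            ("r1", "r2"), ("c1", "c2"),
            np.array([[10, 20], [20, 40]]),
        )
        stat, df = chi_square(t)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_diagonal_two_by_two(self):
        t = ContingencyTable(
            ("r1", "r2"), ("c1", "c2"), np.array([[10, 0], [0, 10]])
        )
        stat, df = chi_square(t)
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_zero_margin_rejected(self):
        t = ContingencyTable(
            ("r1", "r2"), ("c1", "c2"), np.array([[10, 0], [20, 0]])
        )
        with pytest.raises(ValueError, match="zero row/column margin"):
            chi_square(t)

    def test_matches_scipy_on_random_tables(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(20):
            counts = rng.integers(1, 40, size=(3, 4))
            t = ContingencyTable(
                tuple("abc"), tuple("wxyz"), counts
            )
            stat, df = chi_square(t)
            ref = chi2_contingency(counts, correction=False)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert df == ref.dof


class TestCrossTabulate:
    def test_identical_labels_give_diagonal(self):
        t = cross_tabulate([1, 2, 1, 3], [1, 2, 1, 3])
        assert np.all(t.counts == np.diag(np.diag(t.counts)))

    def test_small_example(self):
        t = cross_tabulate([1, 1, 2], ["a", "b", "b"])
        np.testing.assert_array_equal(t.counts, [[1, 1], [0, 1]])

    def test_margins_equal_label_frequencies(self, rng):
        a = rng.integers(0, 3, size=40)
        b = rng.integers(0, 4, size=40)
        t = cross_tabulate(a, b)
        assert sorted(t.counts.sum(axis=1)) == sorted(
            np.bincount(a)[np.bincount(a) > 0]
        )
        assert t.total == 40

    def test_renaming_invariance_of_external_indices(self, rng):
        a = rng.integers(0, 3, size=50)
        b = rng.integers(0, 3, size=50)
        a2 = np.array([{0: "z", 1: "y", 2: "x"}[v] for v in a])
        b2 = b + 100
        assert adjusted_rand(a, b) == pytest.approx(adjusted_rand(a2, b2))
        assert fowlkes_mallows(a, b) == pytest.approx(fowlkes_mallows(a2, b2))
        assert purity(a, b) == pytest.approx(purity(a2, b2))
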