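"""Linkage, dendrogram descriptors, cuts, ultrametric round trips, Newick."""

import numpy as np
import pytest
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from trajensemble.distances import DistanceMatrix, rescale
from trajensemble.hierarchy import (
    Dendrogram,
    UltrametricMatrix,
    complete_linkage,
    cophenetic_matrix,
    cut,
    dendrogram_from_ultrametric,
    is_ultrametric,
    linkage,
    membership_divergence_matrix,
    read_newick,
    write_newick,
)

from conftest import random_dendrogram, random_distance_matrix


class TestLinkage:
    def test_two_leaves(self):
        d = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        h = complete_linkage(d)
        assert h.merges == ((0, 1, 3.0),)

    def test_three_point_hand_example(self, three_point_dendrogram):
        # D(1,2)=1, D(1,3)=5, D(2,3)=4: merge {1,2} at 1, then all at 5
        assert three_point_dendrogram.merges == ((0, 1, 1.0), (3, 2, 5.0))

    def test_heights_non_decreasing(self, rng):
        for _ in range(50):
            h = random_dendrogram(rng, int(rng.integers(2, 15)))
            assert np.all(np.diff(h.heights) >= -1e-12)

    def test_matches_scipy_on_distinct_distances(self, rng):
        """Cross-check against scipy complete linkage: cophenetic matrices
        must agree whenever distances are distinct (no tie ambiguity)."""
        for _ in range(25):
            d = random_distance_matrix(rng, int(rng.integers(3, 12)))
            ours = cophenetic_matrix(complete_linkage(d)).matrix
            z = sch.linkage(squareform(d.matrix), method="complete")
            theirs = squareform(sch.cophenet(z))
            np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_single_and_average_methods(self, rng):
        d = random_distance_matrix(rng, 8)
        for method in ("single", "average"):
            ours = cophenetic_matrix(linkage(d, method=method)).matrix
            z = sch.linkage(squareform(d.matrix), method=method)
            np.testing.assert_allclose(
                ours, squareform(sch.cophenet(z)), rtol=1e-12
            )

    def test_too_few_leaves(self):
        with pytest.raises(ValueError, match="at least 2"):
            complete_linkage(DistanceMatrix(("a",), np.zeros((1, 1))))


class TestDescriptors:
    def test_two_leaf_cophenetic(self):
        d = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        m = cophenetic_matrix(complete_linkage(d)).matrix
        assert m[0, 1] == 3.0 and m[0, 0] == 0.0

    def test_three_point_cophenetic(self, three_point_dendrogram):
        m = cophenetic_matrix(three_point_dendrogram).matrix
        assert m[0, 1] == 1.0
        assert m[0, 2] == m[1, 2] == 5.0

    def test_cophenetic_is_ultrametric(self, rng):
        for _ in range(20):
            h = random_dendrogram(rng, int(rng.integers(2, 15)))
            ok, _ = is_ultrametric(cophenetic_matrix(h).matrix)
            assert ok

    def test_complete_linkage_heights_dominate_distances(self, rng):
        for _ in range(20):
            d = random_distance_matrix(rng, int(rng.integers(3, 12)))
            coph = cophenetic_matrix(complete_linkage(d)).matrix
            assert np.all(coph >= d.matrix - 1e-12)

    def test_membership_divergence_two_and_three(self, three_point_dendrogram):
        d2 = DistanceMatrix(("a", "b"), np.array([[0.0, 3.0], [3.0, 0.0]]))
        m2 = membership_divergence_matrix(complete_linkage(d2)).matrix
        assert m2[0, 1] == 2.0
        m3 = membership_divergence_matrix(three_point_dendrogram).matrix
        assert m3[0, 1] == 2.0
        assert m3[0, 2] == m3[1, 2] == 3.0

    def test_membership_divergence_root_is_n(self, rng):
        h = random_dendrogram(rng, 9)
        m = membership_divergence_matrix(h).matrix
        a, b, _ = h.merges[-1]
        sets = h.leaf_sets()
        i, j = min(sets[a]), min(sets[b])
        assert m[i, j] == 9.0


class TestCut:
    def test_extremes(self, rng):
        h = random_dendrogram(rng, 7)
        assert set(cut(h, 1)) == {1}
        assert sorted(cut(h, 7)) == list(range(1, 8))

    def test_three_point_two_groups(self, three_point_dendrogram):
        np.testing.assert_array_equal(
            cut(three_point_dendrogram, 2), [1, 1, 2]
        )

    def test_out_of_range(self, three_point_dendrogram):
        with pytest.raises(ValueError, match="k must be"):
            cut(three_point_dendrogram, 4)

    def test_invariant_under_rescaling(self, rng):
        for _ in range(10):
            d = random_distance_matrix(rng, 10)
            h1 = complete_linkage(d)
            h2 = complete_linkage(rescale(d, 300.0))
            for k in (2, 3, 5):
                np.testing.assert_array_equal(cut(h1, k), cut(h2, k))

    def test_labels_numbered_by_smallest_leaf(self, rng):
        h = random_dendrogram(rng, 8)
        labels = cut(h, 3)
        firsts = [int(np.flatnonzero(labels == c)[0]) for c in (1, 2, 3)]
        assert firsts == sorted(firsts)


class TestIsUltrametric:
    def test_violating_triple_reported(self):
        m = np.array([[0, 1, 2], [1, 0, 4], [2, 4, 0]], dtype=float)
        ok, worst = is_ultrametric(m)
        assert not ok
        i, j, k = worst
        assert m[i, k] > max(m[i, j], m[j, k])

    def test_trivial_sizes(self):
        ok, _ = is_ultrametric(np.zeros((1, 1)))
        assert ok
        with pytest.raises(ValueError, match="square"):
            is_ultrametric(np.zeros((2, 3)))


class TestUltrametricRoundTrip:
    def test_three_point_reconstruction(self):
        m = np.array([[0, 1, 5], [1, 0, 5], [5, 5, 0]], dtype=float)
        h = dendrogram_from_ultrametric(
            UltrametricMatrix(("a", "b", "c"), m)
        )
        assert h.merges == ((0, 1, 1.0), (3, 2, 5.0))

    def test_constant_matrix_merges_sequentially(self):
        m = np.full((4, 4), 7.0)
        np.fill_diagonal(m, 0.0)
        h = dendrogram_from_ultrametric(UltrametricMatrix(tuple("abcd"), m))
        assert all(height == 7.0 for _, _, height in h.merges)
        assert len(h.merges) == 3

    def test_non_ultrametric_rejected(self):
        d = DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 1, 2], [1, 0, 4], [2, 4, 0]], dtype=float),
        )
        with pytest.raises(ValueError, match="not ultrametric"):
            dendrogram_from_ultrametric(d)

    def test_bijection_on_1000_random_hierarchies(self, rng):
        """Totally indexed hierarchies are in bijection with ultrametrics:
        cophenetic -> reconstruct -> cophenetic is the identity."""
        for _ in range(1000):
            h = random_dendrogram(rng, int(rng.integers(2, 13)))
            coph = cophenetic_matrix(h)
            h2 = dendrogram_from_ultrametric(coph)
            np.testing.assert_array_equal(
                cophenetic_matrix(h2).matrix, coph.matrix
            )


class TestNewick:
    def test_round_trip_topology_and_heights(self, rng):
        for _ in range(25):
            h = random_dendrogram(rng, int(rng.integers(2, 12)))
            back = read_newick(write_newick(h))
            assert set(back.leaves) == set(h.leaves)
            coph_a = cophenetic_matrix(h)
            coph_b = cophenetic_matrix(back)
            perm = [back.leaves.index(x) for x in h.leaves]
            np.testing.assert_allclose(
                coph_b.matrix[np.ix_(perm, perm)], coph_a.matrix, rtol=1e-9
            )

    def test_file_round_trip(self, tmp_path, three_point_dendrogram):
        path = tmp_path / "tree.nwk"
        write_newick(three_point_dendrogram, path)
        back = read_newick(path)
        assert back.merges == three_point_dendrogram.merges

    def test_header_comment_is_ignored(self, three_point_dendrogram):
        text = write_newick(three_point_dendrogram)
        assert text.startswith("[")
        assert read_newick(text).n_leaves == 3

    def test_rejects_unrepresentable_leaf_names(self):
        h = Dendrogram(leaves=("a b",), merges=())
        with pytest.raises(ValueError, match="not representable"):
            write_newick(h)


class TestDendrogramValidation:
    def test_merge_count(self):
        with pytest.raises(ValueError, match="require"):
            Dendrogram(leaves=("a", "b"), merges=())

    def test_decreasing_heights_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            Dendrogram(
                leaves=("a", "b", "c"),
                merges=((0, 1, 5.0), (3, 2, 1.0)),
            )

    def test_node_reuse_rejected(self):
        with pytest.raises(ValueError, match="merged twice"):
            Dendrogram(
                leaves=("a", "b", "c"),
                merges=((0, 1, 1.0), (0, 2, 2.0)),
            )
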