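"""Distances, native linkage vs the first-principles oracle, and flat cuts."""

import numpy as np
import pytest

from aaclust.cluster import (
    Dendrogram,
    DistanceMatrix,
    MONOTONE_SCHEMES,
    SCHEMES,
    cut,
    euclidean_condensed,
    linkage,
    naive_linkage,
    read_merges,
    write_merges,
)


def embed_1d(values):
    """Points on the A axis of the 20-dim frequency space."""
    X = np.zeros((len(values), 20))
    X[:, 0] = values
    return X


def assert_same_dendrogram(a: Dendrogram, b: Dendrogram, tol=1e-9):
    assert a.n_leaves == b.n_leaves
    assert np.array_equal(a.merges[:, :2], b.merges[:, :2])
    assert np.array_equal(a.merges[:, 3], b.merges[:, 3])
    assert np.allclose(a.merges[:, 2], b.merges[:, 2], atol=tol)


def random_frequency_rows(rng, n):
    return rng.dirichlet(np.ones(20) * 0.5, n)


class TestEuclidean:
    def test_identical_rows_have_zero_distance(self):
        X = np.tile(np.full(20, 0.05), (2, 1))
        assert euclidean_condensed(X).condensed[0] == 0.0

    def test_two_unit_coordinates(self):
        X = np.zeros((2, 20))
        X[0, 0] = 1.0  # all A
        X[1, 1] = 1.0  # all C
        assert euclidean_condensed(X).condensed[0] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_matches_per_pair_recomputation(self, rng):
        X = random_frequency_rows(rng, 12)
        d = euclidean_condensed(X)
        k = 0
        for i in range(12):
            for j in range(i + 1, 12):
                naive = np.sqrt(((X[i] - X[j]) ** 2).sum())
                assert d.condensed[k] == pytest.approx(naive, abs=1e-12)
                k += 1

    def test_nonfinite_rejected(self):
        X = np.zeros((3, 20))
        X[1, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            euclidean_condensed(X)


class TestWorkedExamples:
    """Hand-agglomerated 1-D points {0, 1, 3}."""

    @pytest.fixture
    def dist_013(self):
        return euclidean_condensed(embed_1d([0, 1, 3]))

    def test_single(self, dist_013):
        d = linkage(dist_013, "single")
        assert np.allclose(d.merges, [[0, 1, 1, 2], [2, 3, 2, 3]])

    def test_complete(self, dist_013):
        d = linkage(dist_013, "complete")
        assert np.allclose(d.merges, [[0, 1, 1, 2], [2, 3, 3, 3]])

    def test_ward_two_points_merge_at_their_distance(self, rng):
        X = random_frequency_rows(rng, 2)
        d = euclidean_condensed(X)
        dend = linkage(d, "ward")
        assert dend.merges[0, 2] == pytest.approx(d.condensed[0], abs=1e-12)

    def test_naive_centroid_three_collinear_points(self):
        d = euclidean_condensed(embed_1d([0.0, 0.1, 0.3]))
        dend = naive_linkage(d, "centroid")
        # second merge height = distance from centroid of {0, 0.1} to 0.3
        assert dend.merges[1, 2] == pytest.approx(0.3 - 0.05, abs=1e-12)
        assert_same_dendrogram(dend, linkage(d, "centroid"))


class TestOracleEquivalence:
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_linkage_equals_naive(self, rng, scheme):
        for _ in range(8):
            n = int(rng.integers(3, 41))
            d = euclidean_condensed(random_frequency_rows(rng, n))
            assert_same_dendrogram(linkage(d, scheme), naive_linkage(d, scheme))

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_matches_scipy_cophenetic_distances(self, rng, scheme):
        from scipy.cluster.hierarchy import cophenet
        from scipy.cluster.hierarchy import linkage as scipy_linkage

        for _ in range(5):
            n = int(rng.integers(4, 31))
            d = euclidean_condensed(random_frequency_rows(rng, n))
            mine = linkage(d, scheme)
            Z = scipy_linkage(d.condensed, method=scheme)
            assert np.allclose(cophenet(mine.merges), cophenet(Z), atol=1e-8)


class TestInvariants:
    def test_single_linkage_heights_equal_mst_edges(self, rng):
        from scipy.sparse.csgraph import minimum_spanning_tree

        for _ in range(10):
            n = int(rng.integers(3, 31))
            d = euclidean_condensed(random_frequency_rows(rng, n))
            heights = np.sort(linkage(d, "single").heights)
            mst = minimum_spanning_tree(d.as_square()).toarray()
            mst_edges = np.sort(mst[mst > 0])
            assert np.allclose(heights, mst_edges, atol=1e-9)

    @pytest.mark.parametrize("scheme", sorted(MONOTONE_SCHEMES))
    def test_monotone_heights(self, rng, scheme):
        for _ in range(5):
            d = euclidean_condensed(random_frequency_rows(rng, 25))
            dend = linkage(d, scheme)
            assert np.all(np.diff(dend.heights) >= -1e-12)
            assert not dend.has_inversions()

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_permutation_invariance(self, rng, scheme):
        n = 15
        X = random_frequency_rows(rng, n)
        perm = rng.permutation(n)
        base = linkage(euclidean_condensed(X), scheme)
        permuted = linkage(euclidean_condensed(X[perm]), scheme)
        # compare leaf partitions at every level via sets of leaf-label sets
        assert _clade_sets(base, list(range(n))) == _clade_sets(
            permuted, list(np.argsort(np.argsort(perm)))  # inverse permutation
        )

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_scale_equivariance(self, rng, scheme):
        d = euclidean_condensed(random_frequency_rows(rng, 18))
        scaled = DistanceMatrix(d.n, d.condensed * 3.5)
        h1 = linkage(d, scheme).heights
        h2 = linkage(scaled, scheme).heights
        assert np.allclose(h2, 3.5 * h1, atol=1e-9)


def _clade_sets(dend: Dendrogram, labels):
    """Frozenset of each merge's leaf-label set."""
    n = dend.n_leaves
    sets = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for k, (a, b, _h, _s) in enumerate(dend.merges):
        sets[n + k] = sets[int(a)] | sets[int(b)]
        out.add(sets[n + k])
    return out


class TestCut:
    @pytest.fixture
    def dend_013(self):
        return linkage(euclidean_condensed(embed_1d([0, 1, 3])), "single")

    def test_k1_all_together(self, dend_013):
        assert np.array_equal(cut(dend_013, 1), [0, 0, 0])

    def test_kn_all_singletons(self, dend_013):
        assert np.array_equal(cut(dend_013, 3), [0, 1, 2])

    def test_k2_splits_off_far_point(self, dend_013):
        assert np.array_equal(cut(dend_013, 2), [0, 0, 1])

    def test_k_out_of_range(self, dend_013):
        for k in (0, 4):
            with pytest.raises(ValueError, match="out of range"):
                cut(dend_013, k)


class TestValidationAndIO:
    def test_unknown_scheme(self):
        d = euclidean_condensed(embed_1d([0, 1]))
        with pytest.raises(ValueError, match="unknown linkage scheme"):
            linkage(d, "mcquitty")

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            linkage(DistanceMatrix(1, np.array([])), "ward")

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            linkage(DistanceMatrix(2, np.array([-0.1])), "ward")

    def test_merge_table_round_trip(self, rng, tmp_path):
        d = euclidean_condensed(random_frequency_rows(rng, 20))
        dend = linkage(d, "average")
        path = tmp_path / "merges.tsv"
        write_merges(dend, path)
        back = read_merges(path)
        assert back.n_leaves == dend.n_leaves
        assert np.array_equal(back.merges, dend.merges)  # exact float round trip
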