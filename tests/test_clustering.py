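"""Jaccard / Ward / min-size clustering against hand values and the scipy
reference oracle."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from proteograph import (
    FunctionalClusterer,
    cluster_biomarkers,
    cut_at_min_size,
    jaccard_distance_matrix,
    ward_linkage,
)
from proteograph.simulate import SimulationConfig, generate_incidence, generate_network


def _random_incidence(rng, p=8, g=40):
    inc = (rng.random((p, g)) < 0.4).astype(int)
    for i in range(p):
        if inc[i].sum() == 0:
            inc[i, rng.integers(g)] = 1
    for c in range(g):
        while inc[:, c].sum() < 2:
            inc[rng.integers(p), c] = 1
    return inc


class TestJaccardDistance:
    def test_identical_rows_distance_zero(self):
        inc = np.array([[1, 1, 0], [1, 1, 0]])
        assert jaccard_distance_matrix(inc)[0, 1] == 0.0

    def test_disjoint_rows_distance_one(self):
        inc = np.array([[1, 0], [0, 1]])
        assert jaccard_distance_matrix(inc)[0, 1] == 1.0

    def test_hand_set_arithmetic(self):
        inc = np.array([[1, 1, 0], [1, 0, 1]])
        assert jaccard_distance_matrix(inc)[0, 1] == pytest.approx(2 / 3)

    def test_zero_row_names_protein(self):
        inc = np.array([[1, 0], [0, 0]])
        with pytest.raises(ValueError, match="P2"):
            jaccard_distance_matrix(inc, protein_ids=["P1", "P2"])

    def test_matrix_properties(self, rng):
        D = jaccard_distance_matrix(_random_incidence(rng))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert np.all((D >= 0) & (D <= 1))


class TestWardLinkage:
    def test_two_leaves_merge_at_their_distance(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        Z = ward_linkage(D)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.4)
        assert Z[0, 3] == 2

    def test_tight_pairs_merge_before_top(self):
        D = np.full((4, 4), 0.9)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.1
        D[2, 3] = D[3, 2] = 0.1
        Z = ward_linkage(D)
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.1)
        assert Z[2, 2] > 0.5

    def test_rejects_nonsquare(self):
        with pytest.raises(ValueError):
            ward_linkage(np.zeros((2, 3)))

    def test_equal_distance_merges_break_ties_lexicographically(self):
        # Ward output is only unique up to tie order; ours is deterministic:
        # the smallest (i, j) pair merges first
        D = np.full((4, 4), 0.8)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.2
        D[2, 3] = D[3, 2] = 0.2
        Z = ward_linkage(D)
        assert (int(Z[0, 0]), int(Z[0, 1])) == (0, 1)
        assert (int(Z[1, 0]), int(Z[1, 1])) == (2, 3)

    @staticmethod
    def _tie_free_jaccard(seed):
        # dendrograms under tied dissimilarities are tie-break-dependent
        # (Jaccard fractions collide constantly at p=8), so a deterministic
        # microscopic jitter breaks ties before the oracle comparison
        local = np.random.default_rng(seed)
        D = jaccard_distance_matrix(_random_incidence(local))
        jitter = local.random(D.shape) * 1e-7
        jitter = np.triu(jitter, 1)
        D = D + jitter + jitter.T
        d = squareform(D, checks=False)
        assert len(np.unique(d)) == len(d)
        return D

    def test_matches_scipy_on_random_jaccard_matrices(self):
        # same merge heights and identical flat clusterings at every cut
        for seed in range(20):
            D = self._tie_free_jaccard(seed)
            ours = ward_linkage(D)
            ref = linkage(squareform(D, checks=False), method="ward")
            assert np.allclose(np.sort(ours[:, 2]), np.sort(ref[:, 2]), atol=1e-10)
            for height in ours[:, 2]:
                for cut in (height - 1e-9, height + 1e-9):
                    a = fcluster(ours, cut, criterion="distance")
                    b = fcluster(ref, cut, criterion="distance")
                    # identical partitions up to label names
                    pairs_a = a[:, None] == a[None, :]
                    pairs_b = b[:, None] == b[None, :]
                    assert np.array_equal(pairs_a, pairs_b)


class TestCutAtMinSize:
    def test_two_leaves_single_cluster(self):
        Z = ward_linkage(np.array([[0.0, 0.3], [0.3, 0.0]]))
        assignment = cut_at_min_size(Z, 2, min_size=2)
        assert assignment.clusters == [[0, 1]]

    def test_two_tight_pairs_cut_between(self):
        D = np.full((4, 4), 0.9)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.1
        D[2, 3] = D[3, 2] = 0.1
        assignment = cut_at_min_size(ward_linkage(D), 4, min_size=2)
        assert sorted(map(sorted, assignment.clusters)) == [[0, 1], [2, 3]]

    def test_late_joining_singleton_absorbed(self):
        # leaf 4 stays a singleton until the root merge; the cut must rise
        # past it so no singleton is emitted
        D = np.full((5, 5), 0.95)
        np.fill_diagonal(D, 0.0)
        D[0, 1] = D[1, 0] = 0.1
        D[2, 3] = D[3, 2] = 0.2
        assignment = cut_at_min_size(ward_linkage(D), 5, min_size=2)
        assert min(assignment.sizes) >= 2
        assert sum(assignment.sizes) == 5

    def test_min_size_larger_than_p_rejected(self):
        Z = ward_linkage(np.array([[0.0, 0.3], [0.3, 0.0]]))
        with pytest.raises(ValueError):
            cut_at_min_size(Z, 2, min_size=3)

    def test_no_singletons_on_random_incidence(self, rng):
        for seed in range(25):
            local = np.random.default_rng(100 + seed)
            inc = _random_incidence(local, p=int(local.integers(6, 14)))
            assignment = cluster_biomarkers(inc)
            assert min(assignment.sizes) >= 2


class TestClusterBiomarkers:
    def test_identical_annotations_single_cluster(self):
        inc = np.tile([1, 0, 1], (5, 1))
        assignment = cluster_biomarkers(inc)
        assert assignment.m == 1 and assignment.sizes == [5]

    def test_block_incidence_recovers_blocks(self):
        inc = np.zeros((12, 6), dtype=int)
        for b in range(3):
            inc[4 * b:4 * b + 4, 2 * b:2 * b + 2] = 1
        assignment = cluster_biomarkers(inc)
        assert sorted(map(sorted, assignment.clusters)) == [
            list(range(4 * b, 4 * b + 4)) for b in range(3)
        ]

    def test_permutation_equivariance(self, rng):
        inc = _random_incidence(rng, p=10)
        base = cluster_biomarkers(inc).labels()
        perm = rng.permutation(10)
        permuted = cluster_biomarkers(inc[perm]).labels()
        # same partition after mapping positions back to protein identities
        pairs_base = base[:, None] == base[None, :]
        pairs_perm = np.zeros_like(pairs_base)
        for a in range(10):
            for b in range(10):
                pairs_perm[perm[a], perm[b]] = permuted[a] == permuted[b]
        assert np.array_equal(pairs_base, pairs_perm)

    def test_column_permutation_invariance(self, rng):
        inc = _random_incidence(rng, p=9)
        base = cluster_biomarkers(inc).labels()
        shuffled = cluster_biomarkers(inc[:, rng.permutation(inc.shape[1])]).labels()
        assert np.array_equal(base[:, None] == base[None, :],
                              shuffled[:, None] == shuffled[None, :])

    def test_recovers_planted_partition_from_generated_incidence(self):
        cfg = SimulationConfig(p=24, m=4, n=10, seed=3)
        _, clusters = generate_network(cfg)
        inc = generate_incidence(clusters, g_per_cluster=3, overlap_rate=0.0, seed=3)
        recovered = cluster_biomarkers(inc.values)
        assert sorted(map(sorted, recovered.clusters)) == sorted(
            map(sorted, clusters.clusters)
        )

    def test_estimator_api(self, rng):
        inc = _random_incidence(rng, p=10)
        est = FunctionalClusterer(metric="jaccard", min_size=2).fit(inc)
        assert est.labels_.shape == (10,)
        assert est.linkage_.shape == (9, 4)
        with pytest.raises(ValueError, match="unknown metric"):
            FunctionalClusterer(metric="chebyshev").fit(inc)

    def test_alternate_metrics_run(self, rng):
        inc = _random_incidence(rng, p=10)
        for metric in ("cosine", "euclidean", "cityblock"):
            assignment = cluster_biomarkers(inc, metric=metric)
            assert min(assignment.sizes) >= 2
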