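"""Dissimilarity metric, redundancy scan, Ward tree, k-means+BIC, classical MDS."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from radpop.genotype_io import MISSING, GenotypeMatrix
from radpop.distance_clustering import (
    DistanceMatrix,
    UndefinedPairError,
    classical_mds,
    cut_tree,
    dissimilarity,
    kmeans_bic,
    redundancy_scan,
    tree_to_newick,
    ward_tree,
)
from radpop.synthetic_panel import SimulationConfig, simulate_panel

from conftest import make_loci, random_matrix


class TestDissimilarity:
    def test_identical_accessions_are_exactly_zero(self):
        dosage = np.array([[0, 1, 2, 0], [0, 1, 2, 0]], dtype=np.int8)
        gm = GenotypeMatrix(samples=["a", "b"], loci=make_loci(4), dosage=dosage)
        assert dissimilarity(gm).d[0, 1] == 0.0

    def test_opposite_homozygotes_are_one(self):
        dosage = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        gm = GenotypeMatrix(samples=["a", "b"], loci=make_loci(3), dosage=dosage)
        assert dissimilarity(gm).d[0, 1] == 1.0

    def test_hand_computed_mixed_pair(self):
        """(0,2,1,MISSING) vs (0,0,2,1): shared loci contribute 0, 1, 0.5."""
        dosage = np.array([[0, 2, 1, MISSING], [0, 0, 2, 1]], dtype=np.int8)
        gm = GenotypeMatrix(samples=["a", "b"], loci=make_loci(4), dosage=dosage)
        assert dissimilarity(gm).d[0, 1] == pytest.approx(0.5)

    def test_no_shared_loci_raises_unless_allowed(self):
        dosage = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        gm = GenotypeMatrix(samples=["a", "b"], loci=make_loci(2), dosage=dosage)
        with pytest.raises(UndefinedPairError):
            dissimilarity(gm)
        dm = dissimilarity(gm, allow_undefined=True)
        assert np.isnan(dm.d[0, 1])

    def test_triangle_inequality_on_complete_data(self, rng):
        gm = random_matrix(rng, n=12, L=60, missing_rate=0.0)
        d = dissimilarity(gm).d
        for _ in range(200):
            i, j, k = rng.choice(12, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestRedundancy:
    def test_planted_duplicates_detected_below_default_threshold(self):
        gm, _, truth = simulate_panel(
            SimulationConfig(K=2, n_per_pop=25, L=1000, n_duplicates=2,
                             missing_rate=0.0, seed=13)
        )
        scan = redundancy_scan(dissimilarity(gm), threshold=0.005)
        found = {frozenset(p) for p in zip(scan["sample_a"], scan["sample_b"])}
        for a, b in truth.duplicate_pairs:
            assert frozenset((gm.samples[a], gm.samples[b])) in found

    def test_threshold_zero_reports_only_exact_zeros(self):
        dosage = np.array([[0, 1], [0, 1], [2, 1]], dtype=np.int8)
        gm = GenotypeMatrix(samples=["a", "b", "c"], loci=make_loci(2), dosage=dosage)
        scan = redundancy_scan(dissimilarity(gm), threshold=1e-12)
        assert len(scan) == 1 and scan.loc[0, "redundant"]

    def test_empty_when_nothing_close(self, rng):
        gm = random_matrix(rng, n=8, L=100, missing_rate=0.0)
        assert redundancy_scan(dissimilarity(gm), threshold=1e-6).empty


class TestWard:
    def test_two_points_single_merge(self):
        dm = DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 0.4], [0.4, 0.0]]))
        Z = ward_tree(dm)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.4)

    def test_collinear_points_merge_closest_first(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        Z = ward_tree(DistanceMatrix(labels=list("abc"), d=d))
        assert Z[0, 2] == pytest.approx(1.0)
        assert set(Z[0, :2].astype(int)) <= {0, 1, 2}

    def test_heights_monotone_and_permutation_isomorphic(self, rng):
        gm = random_matrix(rng, n=15, L=80, missing_rate=0.0)
        dm = dissimilarity(gm)
        Z = ward_tree(dm)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)
        perm = rng.permutation(15)
        dm_p = DistanceMatrix(
            labels=[dm.labels[i] for i in perm], d=dm.d[np.ix_(perm, perm)]
        )
        Zp = ward_tree(dm_p)
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(Zp[:, 2]), atol=1e-10)

    def test_cut_recovers_two_simulated_populations(self):
        gm, _, truth = simulate_panel(
            SimulationConfig(K=2, n_per_pop=30, L=800, F_k=0.4,
                             admixed_fraction=0.0, n_private=0, n_duplicates=0,
                             seed=21)
        )
        labels = cut_tree(ward_tree(dissimilarity(gm)), k=2)
        assert adjusted_rand_score(truth.pop_labels, labels) >= 0.95

    def test_newick_serialization_well_formed(self, rng):
        gm = random_matrix(rng, n=6, L=40, missing_rate=0.0)
        dm = dissimilarity(gm)
        nwk = tree_to_newick(ward_tree(dm), dm.labels)
        assert nwk.endswith(";") and nwk.count("(") == 5
        for s in dm.labels:
            assert s in nwk


class TestKmeansBic:
    def test_two_separated_blobs_give_k2(self, rng):
        blob1 = rng.normal(0, 1, size=(40, 2))
        blob2 = rng.normal(0, 1, size=(40, 2)) + 20.0  # 10 sigma per axis
        coords = np.vstack([blob1, blob2])
        _, best = kmeans_bic(coords, range(1, 7), restarts=20, seed=3)
        assert best.k == 2

    def test_k1_baseline_computable(self, rng):
        sols, _ = kmeans_bic(rng.normal(size=(30, 3)), [1], seed=0)
        assert sols[0].k == 1 and np.isfinite(sols[0].bic)

    def test_duplicated_dataset_same_best_k(self, rng):
        coords = np.vstack(
            [rng.normal(0, 1, size=(25, 2)), rng.normal(12, 1, size=(25, 2))]
        )
        _, best = kmeans_bic(coords, range(1, 6), restarts=10, seed=1)
        _, best_dup = kmeans_bic(np.vstack([coords, coords]), range(1, 6),
                                 restarts=10, seed=1)
        assert best.k == best_dup.k


class TestClassicalMds:
    def test_line_points_embed_exactly_in_1d(self):
        pts = np.array([0.0, 3.0, 5.0])
        d = np.abs(pts[:, None] - pts[None, :])
        coords, eigval = classical_mds(DistanceMatrix(labels=list("abc"), d=d), dims=1)
        got = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
        np.testing.assert_allclose(got, d, atol=1e-10)

    def test_equilateral_triangle_from_equal_distances(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, _ = classical_mds(DistanceMatrix(labels=list("abc"), d=d), dims=2)
        pair = squareform(pdist(coords))
        off = pair[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, off[0], atol=1e-10)

    def test_euclidean_distances_reproduced(self, rng):
        X = rng.normal(size=(20, 4))
        d = squareform(pdist(X))
        coords, eigval = classical_mds(
            DistanceMatrix(labels=[str(i) for i in range(20)], d=d), dims=4
        )
        np.testing.assert_allclose(squareform(pdist(coords)), d, atol=1e-8)

    def test_agrees_with_reference_pcoa(self, rng):
        """Cross-check coordinates against scikit-bio's PCoA (independent
        implementation) up to per-axis sign."""
        from skbio.stats.ordination import pcoa

        gm = random_matrix(rng, n=12, L=80, missing_rate=0.0)
        dm = dissimilarity(gm)
        coords, _ = classical_mds(dm, dims=3)
        ref = pcoa(dm.d, number_of_dimensions=3).samples.to_numpy()
        for a in range(3):
            assert (
                np.allclose(coords[:, a], ref[:, a], atol=1e-8)
                or np.allclose(coords[:, a], -ref[:, a], atol=1e-8)
            )

    def test_mds_plus_kmeans_separates_diverged_populations(self):
        gm, _, truth = simulate_panel(
            SimulationConfig(K=6, n_per_pop=15, L=600, F_k=0.35,
                             admixed_fraction=0.0, n_private=0, n_duplicates=0,
                             seed=17)
        )
        coords, _ = classical_mds(dissimilarity(gm), dims=10)
        sols, _ = kmeans_bic(coords, [6], restarts=20, seed=2)
        ari = adjusted_rand_score(truth.pop_labels, sols[0].assignments)
        assert ari >= 0.9
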