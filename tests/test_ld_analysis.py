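"""Composite r², decay curves vs a brute-force oracle, LD pruning."""

import numpy as np
import pytest

from radpop.genotype_io import MISSING, GenotypeMatrix, Locus
from radpop.ld_analysis import composite_r2, decay_curve, ld_prune
from radpop.synthetic_panel import SimulationConfig, simulate_panel

from conftest import make_loci, random_matrix


class TestCompositeR2:
    def test_identical_columns_are_one(self):
        col = np.array([0, 1, 2, 0, 2])
        assert composite_r2(col, col) == pytest.approx(1.0)

    def test_perfect_repulsion_is_one(self):
        col = np.array([0, 1, 2, 0, 2])
        assert composite_r2(col, 2 - col) == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        """cov = 2/5, var_a = 4/5, var_b = 2/5 -> r² = (4/25)/(8/25) = 0.5;
        cross-checked against the numpy correlation oracle."""
        a = np.array([0, 0, 1, 2, 2])
        b = np.array([0, 1, 1, 1, 2])
        r = np.corrcoef(a, b)[0, 1]
        assert composite_r2(a, b) == pytest.approx(r**2)
        assert composite_r2(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_monomorphic_on_shared_subset_is_nan(self):
        a = np.array([0, 0, 0, MISSING])
        b = np.array([0, 1, 2, 1])
        assert np.isnan(composite_r2(a, b))

    def test_invariant_to_ref_alt_swap(self, rng):
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        if np.var(a) > 0 and np.var(b) > 0:
            assert composite_r2(a, b) == pytest.approx(composite_r2(2 - a, b))
            assert composite_r2(a, b) == pytest.approx(composite_r2(a, 2 - b))


class TestDecayCurve:
    def test_two_loci_single_pair(self):
        loci = [Locus("chr01", 100, "A", "G", "a"), Locus("chr01", 600, "C", "T", "b")]
        dosage = np.array([[0, 0], [1, 1], [2, 2], [0, 1]], dtype=np.int8)
        gm = GenotypeMatrix(samples=list("wxyz"), loci=loci, dosage=dosage)
        curve = decay_curve(gm, max_dist_bp=1000, bin_width_bp=1000)
        assert curve.pair_count.sum() == 1

    def test_bin_means_match_bruteforce_oracle(self, rng):
        """Binned means equal an independent all-pairs enumeration."""
        gm = random_matrix(rng, n=30, L=50, missing_rate=0.05)
        max_dist, width = 30_000, 5_000
        curve = decay_curve(gm, max_dist_bp=max_dist, bin_width_bp=width)
        pos = gm.positions()
        sums = np.zeros(len(curve.bin_edges) - 1)
        counts = np.zeros_like(sums, dtype=int)
        for i in range(gm.n_loci):
            for j in range(i + 1, gm.n_loci):
                d = int(pos[j] - pos[i])
                if d > max_dist:
                    continue
                r2 = composite_r2(gm.dosage[:, i], gm.dosage[:, j])
                if np.isnan(r2):
                    continue
                b = min(d // width, len(sums) - 1)
                sums[b] += r2
                counts[b] += 1
        np.testing.assert_array_equal(curve.pair_count, counts)
        for b in range(len(sums)):
            if counts[b]:
                assert curve.mean_r2[b] == pytest.approx(sums[b] / counts[b])
            else:
                assert np.isnan(curve.mean_r2[b])

    def test_unlinked_background_near_one_over_n(self):
        """Independent loci: mean r² ~ 1/n, flat in distance (n = 100)."""
        gm, _, _ = simulate_panel(
            SimulationConfig(K=1, n_per_pop=100, L=500, F_k=0.2,
                             switch_rate_per_bp=10.0, chrom_lengths=(200_000,),
                             missing_rate=0.0, n_private=0, n_duplicates=0,
                             seed=4)
        )
        curve = decay_curve(gm, max_dist_bp=200_000, bin_width_bp=20_000)
        assert np.nanmean(curve.mean_r2) == pytest.approx(0.01, abs=0.005)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_mosaic_ld_decays_with_distance(self, seed):
        """Founder-mosaic panels: nearest-bin mean r² strictly exceeds the
        farthest bin, and the half-decay distance sits in the 1-5 kb regime."""
        gm, _, _ = simulate_panel(
            SimulationConfig(K=1, n_per_pop=100, L=400, F_k=0.2,
                             switch_rate_per_bp=5e-4, n_founders=6,
                             chrom_lengths=(400_000,), missing_rate=0.0,
                             n_private=0, n_duplicates=0, seed=seed)
        )
        curve = decay_curve(gm, max_dist_bp=50_000, bin_width_bp=2_000)
        filled = np.nonzero(curve.pair_count > 0)[0]
        assert curve.mean_r2[filled[0]] > curve.mean_r2[filled[-1]]
        assert 1_000 <= curve.half_decay_bp <= 5_000


class TestPruning:
    def test_duplicated_locus_loses_exactly_one_copy(self, rng):
        gm = random_matrix(rng, n=20, L=10, missing_rate=0.0)
        dup = gm.dosage.copy()
        dup[:, 5] = dup[:, 4]  # exact duplicate column
        gm2 = GenotypeMatrix(samples=gm.samples, loci=gm.loci, dosage=dup)
        pruned = ld_prune(gm2, r2_max=0.99)
        kept = {loc.id for loc in pruned.loci}
        assert len({"L4", "L5"} & kept) == 1

    def test_independent_loci_untouched(self):
        gm, _, _ = simulate_panel(
            SimulationConfig(K=1, n_per_pop=80, L=100, F_k=0.2,
                             switch_rate_per_bp=10.0, chrom_lengths=(100_000,),
                             missing_rate=0.0, n_private=0, n_duplicates=0,
                             seed=6)
        )
        assert ld_prune(gm, r2_max=0.5).n_loci == gm.n_loci

    def test_pruning_idempotent(self, rng):
        gm, _, _ = simulate_panel(
            SimulationConfig(K=1, n_per_pop=40, L=200, F_k=0.3,
                             switch_rate_per_bp=5e-4, n_founders=6,
                             chrom_lengths=(200_000,), missing_rate=0.0,
                             n_private=0, n_duplicates=0, seed=8)
        )
        once = ld_prune(gm)
        twice = ld_prune(once)
        assert once == twice
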