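"""Admixture EM: analytic degenerate cases, monotone likelihood, recovery,
cross-validation plumbing, membership classification, F_ST."""

import numpy as np
import pytest

from radpop.genotype_io import GenotypeMatrix
from radpop.ancestry_model import (
    AncestryFit,
    align_labels,
    classify_membership,
    cluster_fst,
    cross_validate_K,
    fit_admixture,
    hudson_fst,
)
from radpop.synthetic_panel import SimulationConfig, simulate_panel

from conftest import make_loci, random_matrix


def binom_loglik(dosage, p):
    """Closed-form K=1 log-likelihood at frequencies p."""
    from radpop.genotype_io import MISSING

    ll = 0.0
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        called = col[col != MISSING].astype(float)
        ll += float(np.sum(called * np.log(p[j]) + (2 - called) * np.log(1 - p[j])))
    return ll


class TestFit:
    def test_k1_analytic_optimum(self, rng):
        gm = random_matrix(rng, n=12, L=30, missing_rate=0.1)
        fit = fit_admixture(gm, K=1)
        assert np.allclose(fit.Q, 1.0)
        from radpop.diversity_stats import alt_freqs

        np.testing.assert_allclose(
            fit.F[0], np.clip(alt_freqs(gm), 1e-6, 1 - 1e-6), atol=1e-12
        )
        assert fit.loglik == pytest.approx(binom_loglik(gm.dosage, fit.F[0]))

    def test_separable_two_populations(self):
        """Two populations fixed for opposite alleles: Q converges to the
        0/1 indicator and the likelihood reaches the analytic maximum."""
        n_half, L = 10, 40
        dosage = np.vstack(
            [np.zeros((n_half, L), np.int8), np.full((n_half, L), 2, np.int8)]
        )
        gm = GenotypeMatrix(
            samples=[f"s{i}" for i in range(2 * n_half)],
            loci=make_loci(L),
            dosage=dosage,
        )
        fit = fit_admixture(gm, K=2, restarts=5, seed=1, tol=1e-10)
        truth = np.zeros((2 * n_half, 2))
        truth[:n_half, 0] = 1
        truth[n_half:, 1] = 1
        aligned = align_labels(fit.Q, truth)
        assert np.abs(aligned - truth).max() < 1e-3
        # analytic max: F at the 1e-6 clamp, every entry at prob (1-1e-6)^2-ish
        ll_max = 2 * n_half * L * 2 * np.log(1 - 1e-6)
        assert fit.loglik == pytest.approx(ll_max, abs=1e-4 * abs(ll_max) + 1e-6)

    def test_loglik_monotone_and_rows_stochastic(self, rng):
        gm = random_matrix(rng, n=20, L=60, missing_rate=0.1)
        fit = fit_admixture(gm, K=3, restarts=2, seed=4)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-9)
        assert fit.F.min() >= 1e-6 and fit.F.max() <= 1 - 1e-6

    def test_sample_permutation_equivariance(self, rng):
        """Permuting the samples (and the initial Q rows with them) permutes
        the fitted Q rows identically — the EM update map is equivariant."""
        from radpop.ancestry_model import _em_fit, _masked_counts

        gm = random_matrix(rng, n=15, L=50, missing_rate=0.1)
        G0, G1 = _masked_counts(gm)
        Q0 = rng.dirichlet(np.ones(2), size=15)
        F0 = rng.uniform(0.05, 0.95, size=(2, 50))
        Q, F, _, _ = _em_fit(G0, G1, Q0.copy(), F0.copy(), max_iter=50, tol=0.0)
        perm = rng.permutation(15)
        Qp, Fp, _, _ = _em_fit(
            G0[perm], G1[perm], Q0[perm].copy(), F0.copy(), max_iter=50, tol=0.0
        )
        np.testing.assert_allclose(Qp, Q[perm], atol=1e-10)
        np.testing.assert_allclose(Fp, F, atol=1e-10)

    def test_k_exceeding_samples_rejected(self, rng):
        gm = random_matrix(rng, n=4, L=10)
        with pytest.raises(ValueError):
            fit_admixture(gm, K=5)

    def test_recovers_planted_admixture(self):
        """K=3, F=0.3, Dirichlet(0.1) admixture: mean |Q - Q_true| <= 0.05
        after label alignment."""
        cfg = SimulationConfig(K=3, n_per_pop=30, L=1000, F_k=0.3, alpha=0.1,
                               seed=2, n_private=0, n_duplicates=0)
        gm, _, truth = simulate_panel(cfg)
        fit = fit_admixture(gm, K=3, restarts=3, seed=7)
        aligned = align_labels(fit.Q, truth.Q_true)
        assert np.abs(aligned - truth.Q_true).mean() <= 0.05


class TestCrossValidation:
    def test_two_folds_on_tiny_matrix(self, rng):
        gm = random_matrix(rng, n=8, L=30, missing_rate=0.0)
        cv = cross_validate_K(gm, K_range=[1, 2], folds=2, seed=0,
                              max_iter=50, tol=1e-2)
        assert cv.folds == 2
        assert all(len(v) == 2 for v in cv.fold_scores.values())

    def test_unstructured_panel_prefers_k1(self):
        """A single homogeneous population: held-out deviance is minimized at
        K=1 (extra clusters only overfit)."""
        gm, _, _ = simulate_panel(
            SimulationConfig(K=1, n_per_pop=60, L=400, F_k=0.3,
                             n_private=0, n_duplicates=0, seed=14)
        )
        cv = cross_validate_K(gm, K_range=[1, 2, 3], folds=5, seed=3,
                              max_iter=200, tol=1e-2)
        assert cv.best_K == 1
        assert cv.cv_errors[0] <= cv.cv_errors[2]


class TestMembership:
    def _fit(self, Q):
        return AncestryFit(K=Q.shape[1], Q=np.asarray(Q, float),
                           F=np.full((Q.shape[1], 5), 0.5),
                           loglik_trace=np.array([0.0]), converged=True, seed=0)

    def test_clear_majority_assigned(self):
        assert classify_membership(self._fit(np.array([[0.9, 0.1]]))) == ["K1"]

    def test_below_half_is_admixed(self):
        fit = self._fit(np.array([[0.45, 0.35, 0.20]]))
        assert classify_membership(fit) == ["admixed"]

    def test_exact_tie_is_admixed(self):
        assert classify_membership(self._fit(np.array([[0.5, 0.5]]))) == ["admixed"]


class TestFst:
    def _fit_from_F(self, F):
        K, L = F.shape
        return AncestryFit(K=K, Q=np.ones((1, K)) / K, F=F,
                           loglik_trace=np.array([0.0]), converged=True, seed=0)

    def test_identical_frequencies_zero(self):
        F = np.full((2, 20), 0.3)
        assert cluster_fst(self._fit_from_F(F))[0, 1] == 0.0

    def test_complete_fixation_one(self):
        F = np.vstack([np.full(20, 1 - 1e-6), np.full(20, 1e-6)])
        assert cluster_fst(self._fit_from_F(F))[0, 1] == pytest.approx(1.0, abs=1e-5)

    def test_hudson_recovers_generative_divergence(self):
        gm, _, truth = simulate_panel(
            SimulationConfig(K=2, n_per_pop=100, L=5000, F_k=0.2,
                             admixed_fraction=0.0, missing_rate=0.0,
                             n_private=0, n_duplicates=0, seed=3)
        )
        est = hudson_fst(gm, truth.pop_labels == 0, truth.pop_labels == 1)
        assert est == pytest.approx(0.2, abs=0.03)
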