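"""Maximum-likelihood admixture model: EM fitting, cross-validated K, F_ST.

Model
-----
Each diploid genotype is a binomial draw from an individual- and locus-
specific allele frequency that mixes K cluster frequencies::

    g_ij ~ Binomial(2, pi_ij),   pi_ij = sum_k q_ik f_kj

with Q (n x K, rows on the simplex) the membership proportions and F (K x L)
the cluster ALT-allele frequencies.  The log-likelihood over non-missing
entries is ``l = sum_ij [ g_ij ln pi_ij + (2 - g_ij) ln(1 - pi_ij) ]``.

Fitting is by EM block updates (allele-level responsibilities), which are
guaranteed to increase ``l`` monotonically and preserve row-stochasticity of
Q exactly.  The number of clusters is chosen by masking a random partition
of the non-missing genotype entries into folds, refitting with each fold
hidden and scoring the held-out entries by their mean binomial deviance —
the entry-masking cross-validation scheme popularized by the ADMIXTURE
software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .genotype_io import MISSING, GenotypeMatrix

_F_EPS = 1e-6


@dataclass
class AncestryFit:
    """Fitted admixture model."""

    K: int
    Q: np.ndarray  # (n, K), rows sum to 1
    F: np.ndarray  # (K, L), entries in [1e-6, 1 - 1e-6]
    loglik_trace: np.ndarray
    converged: bool
    seed: int

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class CvResult:
    """Cross-validation over K."""

    K_values: list[int]
    cv_errors: list[float]  # mean held-out deviance per K
    fold_scores: dict[int, list[float]]
    folds: int

    @property
    def best_K(self) -> int:
        return self.K_values[int(np.argmin(self.cv_errors))]


def _masked_counts(gm_or_dosage) -> tuple[np.ndarray, np.ndarray]:
    """(G0, G1): ALT and REF allele counts with missing entries zeroed."""
    dosage = (
        gm_or_dosage.dosage if isinstance(gm_or_dosage, GenotypeMatrix) else gm_or_dosage
    )
    W = dosage != MISSING
    g = dosage.astype(float)
    G0 = np.where(W, g, 0.0)
    G1 = np.where(W, 2.0 - g, 0.0)
    return G0, G1


def _loglik(G0: np.ndarray, G1: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    P = Q @ F
    return float(np.sum(G0 * np.log(P) + G1 * np.log1p(-P)))


def _em_fit(
    G0: np.ndarray,
    G1: np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Run EM from (Q, F); returns (Q, F, loglik trace, converged)."""
    M = np.maximum((G0 + G1).sum(axis=1), 1e-12)  # 2 * non-missing loci per sample
    trace = [_loglik(G0, G1, Q, F)]
    converged = False
    for _ in range(max_iter):
        P = Q @ F
        R = G0 / P
        S = G1 / (1.0 - P)
        # E-step sums, collapsed to matrix products (see module docstring)
        A = Q * (R @ F.T)          # sum_j g a_ijk        -> (n, K)
        B = Q * (S @ (1.0 - F).T)  # sum_j (2-g) b_ijk    -> (n, K)
        FA = F * (Q.T @ R)         # sum_i g a_ijk        -> (K, L)
        FB = (1.0 - F) * (Q.T @ S)
        Q = (A + B) / M[:, None]
        Q /= Q.sum(axis=1, keepdims=True)  # exact renormalization (fp hygiene)
        with np.errstate(invalid="ignore", divide="ignore"):
            F_new = FA / (FA + FB)
        F_new = np.where(np.isfinite(F_new), F_new, F)  # zero-weight cells keep F
        F = np.clip(F_new, _F_EPS, 1.0 - _F_EPS)
        ll = _loglik(G0, G1, Q, F)
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return Q, F, np.asarray(trace), converged


def fit_admixture(
    gm: GenotypeMatrix,
    K: int,
    max_iter: int = 2000,
    tol: float = 1e-4,
    restarts: int = 3,
    seed: int = 0,
) -> AncestryFit:
    """Fit the admixture model by EM, best of ``restarts`` random starts.

    The log-likelihood is non-decreasing along the returned trace.  For
    K = 1 the analytic optimum (observed ALT frequencies) is returned
    directly.  Clusters are reported ordered by total membership so labels
    are reproducible.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > gm.n_samples:
        raise ValueError(f"K={K} exceeds the number of samples ({gm.n_samples})")
    G0, G1 = _masked_counts(gm)
    n, L = G0.shape

    if K == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            phat = G0.sum(axis=0) / np.maximum((G0 + G1).sum(axis=0), 1.0)
        F = np.clip(phat[None, :], _F_EPS, 1.0 - _F_EPS)
        Q = np.ones((n, 1))
        ll = _loglik(G0, G1, Q, F)
        return AncestryFit(K=1, Q=Q, F=F, loglik_trace=np.array([ll]),
                           converged=True, seed=seed)

    best: AncestryFit | None = None
    for r in range(restarts):
        rng = np.random.default_rng((seed, r))
        Q0 = rng.dirichlet(np.ones(K), size=n)
        F0 = rng.uniform(0.05, 0.95, size=(K, L))
        Q, F, trace, conv = _em_fit(G0, G1, Q0, F0, max_iter, tol)
        fit = AncestryFit(K=K, Q=Q, F=F, loglik_trace=trace, converged=conv, seed=seed)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    order = np.argsort(-best.Q.sum(axis=0), kind="stable")
    return AncestryFit(
        K=K,
        Q=best.Q[:, order],
        F=best.F[order, :],
        loglik_trace=best.loglik_trace,
        converged=best.converged,
        seed=seed,
    )


def align_labels(Q_est: np.ndarray, Q_ref: np.ndarray) -> np.ndarray:
    """Column permutation of ``Q_est`` best matching ``Q_ref`` (Hungarian on
    negative column correlations/overlaps); resolves label switching."""
    K = Q_est.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = -float(Q_est[:, a] @ Q_ref[:, b])
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return Q_est[:, perm]


def cross_validate_K(
    gm: GenotypeMatrix,
    K_range: range | list[int] = range(1, 16),
    folds: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-4,
    restarts: int = 1,
) -> CvResult:
    """Choose K by entry-masking cross-validation.

    Non-missing genotype entries are partitioned into ``folds`` random
    masks.  For each fold the masked entries are hidden, the model refitted,
    and the held-out entries scored by their mean binomial deviance
    ``-[g ln pi + (2 - g) ln(1 - pi)] / 2``.  ``CV(K)`` is the mean over
    folds; the best K minimizes it.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    obs_i, obs_j = np.nonzero(gm.dosage != MISSING)
    n_obs = obs_i.size
    fold_of = rng.integers(folds, size=n_obs)
    for f in range(folds):
        if not np.any(fold_of == f):
            raise ValueError(f"fold {f} has zero masked entries")

    K_values = list(K_range)
    fold_scores: dict[int, list[float]] = {K: [] for K in K_values}
    for f in range(folds):
        masked = fold_of == f
        dosage_f = gm.dosage.copy()
        dosage_f[obs_i[masked], obs_j[masked]] = MISSING
        gm_f = GenotypeMatrix(
            samples=list(gm.samples), loci=list(gm.loci), dosage=dosage_f
        )
        g_held = gm.dosage[obs_i[masked], obs_j[masked]].astype(float)
        for K in K_values:
            fit = fit_admixture(
                gm_f, K, max_iter=max_iter, tol=tol, restarts=restarts,
                seed=int(np.random.default_rng((seed, f, K)).integers(2**31)),
            )
            P = (fit.Q @ fit.F)[obs_i[masked], obs_j[masked]]
            P = np.clip(P, _F_EPS, 1.0 - _F_EPS)
            dev = -(g_held * np.log(P) + (2.0 - g_held) * np.log1p(-P)) / 2.0
            fold_scores[K].append(float(dev.mean()))
    cv_errors = [float(np.mean(fold_scores[K])) for K in K_values]
    return CvResult(
        K_values=K_values, cv_errors=cv_errors, fold_scores=fold_scores, folds=folds
    )


def classify_membership(fit: AncestryFit, q_min: float = 0.5) -> list[str]:
    """Assign each sample to its argmax cluster, or ``"admixed"``.

    A sample is admixed when its highest membership coefficient is below
    ``q_min`` (default 0.5); exact ties are classified admixed too.
    """
    out = []
    for row in fit.Q:
        top = np.max(row)
        if top < q_min or np.sum(row == top) > 1:
            out.append("admixed")
        else:
            out.append(f"K{int(np.argmax(row)) + 1}")
    return out


def cluster_fst(fit: AncestryFit) -> np.ndarray:
    """Pairwise Hudson-type F_ST between inferred cluster frequencies.

    Because the cluster frequencies are model parameters (not finite-sample
    estimates) no sampling correction applies::

        F_ST(k, l) = sum_j (f_kj - f_lj)^2
                     / sum_j [ f_kj (1 - f_lj) + f_lj (1 - f_kj) ]

    Diagonal is 0; a pair monomorphic everywhere (zero denominator) is NaN.
    """
    if fit.K < 2:
        raise ValueError("need K >= 2 clusters for pairwise F_ST")
    F = fit.F
    K = fit.K
    out = np.zeros((K, K))
    for k in range(K):
        for l in range(k + 1, K):
            num = float(np.sum((F[k] - F[l]) ** 2))
            den = float(np.sum(F[k] * (1 - F[l]) + F[l] * (1 - F[k])))
            out[k, l] = out[l, k] = num / den if den > 0 else np.nan
    return out


def hudson_fst(gm: GenotypeMatrix, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Empirical Hudson F_ST between two sample groups (ratio of averages).

    Per locus, with sample ALT frequencies p1, p2 over n1, n2 called alleles::

        num_j = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den_j = p1(1-p2) + p2(1-p1)

    and ``F_ST = sum_j num_j / sum_j den_j`` over loci where both groups have
    at least 2 called alleles.
    """
    def freqs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sub = gm.dosage[mask]
        nonmiss = sub != MISSING
        n_alleles = 2.0 * nonmiss.sum(axis=0)
        alt = np.where(nonmiss, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan), n_alleles

    p1, n1 = freqs(np.asarray(mask_a))
    p2, n2 = freqs(np.asarray(mask_b))
    ok = (n1 >= 2) & (n2 >= 2)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def bootstrap_q_se(
    gm: GenotypeMatrix,
    K: int,
    n_boot: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> np.ndarray:
    """Bootstrap-over-loci standard errors of the Q matrix (optional, slow).

    Refits on ``n_boot`` locus resamples, aligns labels to the full-data fit
    and returns the element-wise standard deviation of Q across replicates.
    """
    base = fit_admixture(gm, K, seed=seed, **fit_kwargs)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        idx = np.sort(rng.integers(gm.n_loci, size=gm.n_loci))
        fit = fit_admixture(
            gm.take_loci(idx), K, seed=int(rng.integers(2**31)), **fit_kwargs
        )
        reps.append(align_labels(fit.Q, base.Q))
    return np.std(np.stack(reps), axis=0, ddof=1)
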