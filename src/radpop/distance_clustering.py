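"""Allele-sharing distances, Ward clustering, k-means + BIC, classical MDS.

The dissimilarity index between two accessions is the proportion of
unmatching alleles, averaged over loci where both have a call: per locus,
``|g_a - g_b| / 2`` of the two allele slots differ (0, 0.5 or 1), so two
identical accessions have distance exactly 0.0 and opposite homozygotes at
every locus have distance 1.0.  "Allele-sharing distance" and "dissimilarity
index" are the same quantity (1 minus the allele-sharing proportion); both
names are in common use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .genotype_io import MISSING, GenotypeMatrix


class UndefinedPairError(ValueError):
    """Some sample pair shares no co-non-missing locus."""


@dataclass
class DistanceMatrix:
    """Symmetric accession x accession dissimilarities in [0, 1], zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance diagonal must be exactly 0")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


@dataclass
class ClusterSolution:
    """One k-means solution with its spherical-Gaussian BIC."""

    k: int
    assignments: np.ndarray
    objective: float  # total within-cluster sum of squares
    bic: float


def dissimilarity(gm: GenotypeMatrix, allow_undefined: bool = False) -> DistanceMatrix:
    """Pairwise dissimilarity index from the genotype matrix.

    ``d(a, b) = mean over co-non-missing loci of |g_a - g_b| / 2``.  Pairs
    sharing no locus raise :class:`UndefinedPairError` (NaN if
    ``allow_undefined``).
    """
    G = gm.dosage.astype(float)
    G[gm.dosage == MISSING] = np.nan
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(G[i + 1:] - G[i]) / 2.0  # NaN where either is missing
        shared = np.sum(~np.isnan(diff), axis=1)
        with np.errstate(invalid="ignore"):
            row = np.nansum(diff, axis=1) / shared
        row[shared == 0] = np.nan
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    if np.isnan(d).any() and not allow_undefined:
        bad = [
            (gm.samples[i], gm.samples[j])
            for i, j in zip(*np.nonzero(np.isnan(np.triu(d))))
        ]
        raise UndefinedPairError(f"pairs with no shared non-missing locus: {bad}")
    return DistanceMatrix(labels=list(gm.samples), d=d)


def redundancy_scan(
    dm: DistanceMatrix, threshold: float = 0.005
) -> pd.DataFrame:
    """All unordered pairs with distance below ``threshold``, ascending.

    Exact zeros are flagged ``redundant`` (indistinguishable genotypes);
    small positive values indicate near-duplicates.
    """
    iu, ju = np.triu_indices(dm.n, k=1)
    dist = dm.d[iu, ju]
    hit = np.nonzero(dist < threshold)[0]
    hit = hit[np.argsort(dist[hit], kind="stable")]
    rows = [
        {
            "sample_a": dm.labels[iu[h]],
            "sample_b": dm.labels[ju[h]],
            "distance": float(dist[h]),
            "redundant": bool(dist[h] == 0.0),
        }
        for h in hit
    ]
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "distance", "redundant"])


# ---------------------------------------------------------------------------
# Ward dendrogram
# ---------------------------------------------------------------------------

def ward_tree(dm: DistanceMatrix) -> np.ndarray:
    """Agglomerative Ward linkage on the dissimilarity matrix.

    Uses the Ward.D2 convention (Lance–Williams recurrence applied to the
    distances themselves, squared internally), as implemented by scipy's
    ``linkage(..., method="ward")`` on a condensed distance matrix.  Returns
    the (n-1, 4) scipy linkage matrix; merge heights are non-decreasing.
    """
    if dm.n < 2:
        raise ValueError("need at least 2 samples to build a tree")
    return sch.linkage(dm.condensed(), method="ward")


def cut_tree(linkage: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels (0-based) from cutting the dendrogram at k clusters."""
    return sch.fcluster(linkage, t=k, criterion="maxclust") - 1


def tree_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as Newick, branch lengths from merge heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for m, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + m] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + m] = h
    return nodes[n + len(linkage) - 1] + ";"


# ---------------------------------------------------------------------------
# k-means + BIC
# ---------------------------------------------------------------------------

def kmeans_bic(
    coords: np.ndarray,
    k_range: range | list[int],
    restarts: int = 10,
    seed: int = 0,
) -> tuple[list[ClusterSolution], ClusterSolution]:
    """k-means over a range of k with BIC model choice.

    For each k the best of ``restarts`` k-means++ runs (Lloyd) is kept and
    scored with the classification-likelihood BIC of a shared-variance
    spherical Gaussian mixture evaluated at the hard assignments::

        sigma^2 = WSS / (n d)
        ll      = sum_c n_c ln(n_c / n) - (n d / 2) ln(2 pi sigma^2) - n d / 2
        BIC     = -2 ll + (k d + k) ln(n)

    (k·d centroid coordinates, k-1 mixing weights, 1 variance).  The mixing
    entropy term is what keeps a single Gaussian from being split: a naive
    ``n·d·ln(WSS/(n·d))`` criterion keeps rewarding subdivision of one blob.
    The best k minimizes BIC; k = 1 is the no-clustering baseline.

    Returns (all solutions, best solution).
    """
    coords = np.asarray(coords, dtype=float)
    n, dim = coords.shape
    solutions: list[ClusterSolution] = []
    for k in k_range:
        if k >= n:
            break
        if k == 1:
            centroid = coords.mean(axis=0)
            wss = float(((coords - centroid) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k, init="k-means++", n_init=restarts,
                algorithm="lloyd", random_state=seed,
            ).fit(coords)
            wss = float(km.inertia_)
            labels = km.labels_.astype(int)
        wss = max(wss, 1e-300)  # guard log of a perfectly fit model
        sigma2 = wss / (n * dim)
        counts = np.bincount(labels, minlength=k).astype(float)
        counts = counts[counts > 0]
        ll = (
            float((counts * np.log(counts / n)).sum())
            - 0.5 * n * dim * np.log(2 * np.pi * sigma2)
            - 0.5 * n * dim
        )
        bic = -2.0 * ll + (k * dim + k) * np.log(n)
        solutions.append(
            ClusterSolution(k=k, assignments=labels, objective=wss, bic=float(bic))
        )
    best = min(solutions, key=lambda s: (s.bic, s.k))
    return solutions, best


# ---------------------------------------------------------------------------
# Classical MDS (principal coordinates)
# ---------------------------------------------------------------------------

def classical_mds(
    dm: DistanceMatrix, dims: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates analysis of a distance matrix.

    Double-centers ``-0.5 J D² J``, eigendecomposes, and returns coordinates
    built from the top ``dims`` positive eigenvalues plus the full eigenvalue
    spectrum (negative eigenvalues are reported, never used).  If fewer than
    ``dims`` positive eigenvalues exist the embedding is truncated with a
    warning.  Sign convention: per axis, the largest-magnitude loading is
    made positive.
    """
    import warnings

    D2 = dm.d**2
    n = dm.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(abs(eigval[0]), 1.0)
    n_pos = int(pos.sum())
    use = min(dims, n_pos)
    if use < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; embedding truncated to {use} dims",
            stacklevel=2,
        )
    coords = eigvec[:, :use] * np.sqrt(eigval[:use])
    for a in range(use):
        j = np.argmax(np.abs(coords[:, a]))
        if coords[j, a] < 0:
            coords[:, a] = -coords[:, a]
    return coords, eigval
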