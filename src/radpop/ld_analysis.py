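"""Pairwise linkage disequilibrium, decay curves and LD pruning.

The r² estimator is the squared Pearson correlation of allele dosages over
samples called at both loci (composite LD).  In highly homozygous material —
cultivated tomato runs at ~2% heterozygosity — this coincides with the
haplotype-phase r² while requiring no phasing and staying deterministic.
r² is invariant to swapping the REF/ALT orientation of either locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class DecayCurve:
    """Binned mean r² against inter-locus distance, for one sample group."""

    bin_edges: np.ndarray  # (B + 1,) bp
    mean_r2: np.ndarray  # (B,), NaN for empty bins
    pair_count: np.ndarray  # (B,)
    group: str
    half_decay_bp: float  # NaN if undefined

    def to_frame(self) -> pd.DataFrame:
        mid = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "bin_mid": mid,
                "mean_r2": self.mean_r2,
                "pair_count": self.pair_count,
                "group": self.group,
            }
        )


def composite_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared dosage correlation over samples non-missing at both loci.

    Returns NaN when fewer than two shared samples exist or either locus is
    monomorphic on the shared subset.
    """
    col_a = np.asarray(col_a, dtype=float)
    col_b = np.asarray(col_b, dtype=float)
    shared = (col_a != MISSING) & (col_b != MISSING)
    if shared.sum() < 2:
        return float("nan")
    a, b = col_a[shared], col_b[shared]
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        return float("nan")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov**2 / (va * vb))


def _pairwise_r2_table(
    gm: GenotypeMatrix,
    max_dist_bp: int,
    sample_idx: np.ndarray,
) -> pd.DataFrame:
    """All intra-chromosomal locus pairs within ``max_dist_bp``, with r²."""
    chroms = gm.chromosomes()
    positions = gm.positions()
    sub = gm.dosage[sample_idx, :]
    rows = []
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.nonzero(chroms == chrom)[0]
        pos = positions[idx]
        for ii, j in enumerate(idx):
            for jj in idx[ii + 1:]:
                dist = int(positions[jj] - positions[j])
                if dist > max_dist_bp:
                    break
                rows.append(
                    {
                        "locus_a": gm.loci[j].id,
                        "locus_b": gm.loci[jj].id,
                        "chrom": chrom,
                        "dist_bp": dist,
                        "r2": composite_r2(sub[:, j], sub[:, jj]),
                    }
                )
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "chrom", "dist_bp", "r2"])


def decay_curve(
    gm: GenotypeMatrix,
    max_dist_bp: int = 300_000,
    bin_width_bp: int = 500,
    group_mask: np.ndarray | None = None,
    group: str = "all",
) -> DecayCurve:
    """LD decay curve: binned mean r² of all intra-chromosomal pairs.

    Pairs are scored within the group's samples only; pairs with undefined
    r² (monomorphic on the shared subset) are excluded.  The half-decay
    distance is the smallest bin midpoint at which the mean r² has fallen to
    the midpoint between the maximum bin mean and the far-field level (the
    mean of the last decile of non-empty bins); NaN when the curve never
    crosses that level.
    """
    if group_mask is None:
        sample_idx = np.arange(gm.n_samples)
    else:
        sample_idx = np.nonzero(np.asarray(group_mask))[0]
    if sample_idx.size < 2:
        raise ValueError("group must contain at least 2 samples")
    pairs = _pairwise_r2_table(gm, max_dist_bp, sample_idx)
    pairs = pairs.dropna(subset=["r2"])

    edges = np.arange(0, max_dist_bp + bin_width_bp, bin_width_bp)
    n_bins = len(edges) - 1
    mean_r2 = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    if len(pairs):
        which = np.clip(
            np.digitize(pairs["dist_bp"].to_numpy(), edges) - 1, 0, n_bins - 1
        )
        for b in range(n_bins):
            sel = which == b
            counts[b] = int(sel.sum())
            if counts[b]:
                mean_r2[b] = float(pairs["r2"].to_numpy()[sel].mean())

    half = float("nan")
    filled = np.nonzero(counts > 0)[0]
    if filled.size >= 2:
        vals = mean_r2[filled]
        far = vals[-max(1, filled.size // 10):].mean()
        target = (vals.max() + far) / 2.0
        mids = (edges[:-1] + edges[1:]) / 2.0
        below = filled[vals <= target]
        if below.size:
            half = float(mids[below[0]])
    return DecayCurve(
        bin_edges=edges, mean_r2=mean_r2, pair_count=counts,
        group=group, half_decay_bp=half,
    )


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> GenotypeMatrix:
    """Sliding-window LD pruning; deterministic and idempotent.

    Within each window, while any remaining pair exceeds ``r2_max``, the
    member with the lower MAF is removed (tie: the higher locus index); the
    window then advances by ``step_snps``.  Windows never span chromosomes.
    The sweep is repeated until no further locus is removed (removals shift
    window boundaries, so a single pass is not a fixed point).
    """
    from .diversity_stats import alt_freqs

    p = alt_freqs(gm)
    maf = np.minimum(p, 1 - p)
    chroms = gm.chromosomes()
    keep = np.ones(gm.n_loci, dtype=bool)

    changed_any = True
    while changed_any:
        n_kept_before = int(keep.sum())
        _prune_pass(gm, maf, chroms, keep, window_snps, step_snps, r2_max)
        changed_any = int(keep.sum()) < n_kept_before
    return gm.take_loci(np.nonzero(keep)[0])


def _prune_pass(gm, maf, chroms, keep, window_snps, step_snps, r2_max):
    """One sliding-window sweep over the currently kept loci, in place."""
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.nonzero((chroms == chrom) & keep)[0]
        start = 0
        while start < len(idx):
            window = idx[start:start + window_snps]
            active = [j for j in window if keep[j]]
            changed = True
            while changed and len(active) > 1:
                changed = False
                worst = None  # (r2, removal candidate)
                for a_i in range(len(active)):
                    for b_i in range(a_i + 1, len(active)):
                        a, b = active[a_i], active[b_i]
                        r2 = composite_r2(gm.dosage[:, a], gm.dosage[:, b])
                        if np.isnan(r2) or r2 <= r2_max:
                            continue
                        if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                            drop = a
                        else:
                            drop = b
                        if worst is None or r2 > worst[0]:
                            worst = (r2, drop)
                if worst is not None:
                    keep[worst[1]] = False
                    active.remove(worst[1])
                    changed = True
            if start + window_snps >= len(idx):
                break
            start += step_snps
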