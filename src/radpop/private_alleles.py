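"""Minor-allele-frequency contrast screen for group-private variants.

The screen flags loci whose panel-global minor allele is common inside a
focus germplasm group but rare everywhere else: *contrasting* loci have
group MAF > 0.4 in the focus group and < 0.2 in the complement, the
*most contrasting* tier additionally requires < 0.1 in the complement.
Inequalities are strict, and both group frequencies refer to the same
(panel-global minor) allele, so the contrast is coherent even when the
focus-group value exceeds 0.5.

This is a descriptive threshold rule, not a test; an optional Fisher
exact p-value per locus can be added for triage but plays no role in the
tier assignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, locus_in_region
from .diversity_stats import alt_freqs


def _group_freq_minor(
    gm: GenotypeMatrix, sample_mask: np.ndarray, minor_is_alt: np.ndarray,
    min_group_calls: int = 1,
) -> np.ndarray:
    sub = gm.dosage[sample_mask, :]
    nonmiss = sub != MISSING
    n_called = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_called >= min_group_calls, alt / (2.0 * n_called), np.nan)
    return np.where(minor_is_alt, p_alt, 1.0 - p_alt)


def contrast_screen(
    gm: GenotypeMatrix,
    meta: pd.DataFrame,
    focus_status: str = "da_serbo",
    t_focus: float = 0.4,
    t_rest: float = 0.2,
    t_tight: float = 0.1,
    min_group_calls: int = 1,
    fisher_pvalues: bool = False,
) -> pd.DataFrame:
    """Screen every locus for a focus-vs-rest minor-allele frequency contrast.

    Returns one row per hit (``maf_focus > t_focus`` and ``maf_rest <
    t_rest``, strict), sorted by (chrom, pos), with ``tier`` equal to
    ``"most_contrasting"`` when additionally ``maf_rest < t_tight`` and
    ``"contrasting"`` otherwise.  Loci with an undefined frequency in either
    group are excluded.
    """
    focus_ids = set(meta.loc[meta["status"] == focus_status, "id"])
    focus_mask = np.asarray([s in focus_ids for s in gm.samples])
    if not focus_mask.any():
        raise ValueError(f"focus group {focus_status!r} is empty in this panel")
    rest_mask = ~focus_mask
    if not rest_mask.any():
        raise ValueError("complement group is empty")

    p_global = alt_freqs(gm)
    minor_is_alt = p_global <= 0.5
    maf_focus = _group_freq_minor(gm, focus_mask, minor_is_alt, min_group_calls)
    maf_rest = _group_freq_minor(gm, rest_mask, minor_is_alt, min_group_calls)

    defined = ~np.isnan(maf_focus) & ~np.isnan(maf_rest)
    hit = defined & (maf_focus > t_focus) & (maf_rest < t_rest)
    rows = []
    for j in np.nonzero(hit)[0]:
        loc = gm.loci[j]
        row = {
            "chrom": loc.chrom,
            "pos": loc.pos,
            "id": loc.id,
            "locus_index": int(j),
            "maf_focus": float(maf_focus[j]),
            "maf_rest": float(maf_rest[j]),
            "tier": "most_contrasting" if maf_rest[j] < t_tight else "contrasting",
        }
        if fisher_pvalues:
            row["fisher_p"] = _fisher_p(gm, j, focus_mask, minor_is_alt[j])
        rows.append(row)
    cols = ["chrom", "pos", "id", "locus_index", "maf_focus", "maf_rest", "tier"]
    if fisher_pvalues:
        cols.append("fisher_p")
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _fisher_p(
    gm: GenotypeMatrix, j: int, focus_mask: np.ndarray, minor_is_alt: bool
) -> float:
    """Two-sided Fisher exact p for the minor-allele count contrast (extra
    diagnostic output; not part of the screen definition)."""
    from scipy.stats import fisher_exact

    col = gm.dosage[:, j]
    nonmiss = col != MISSING
    counts = []
    for mask in (focus_mask, ~focus_mask):
        called = mask & nonmiss
        alt = int(col[called].sum())
        total = 2 * int(called.sum())
        minor = alt if minor_is_alt else total - alt
        counts.append((minor, total - minor))
    _, p = fisher_exact(counts)
    return float(p)


def annotate_hits(
    hits: pd.DataFrame, regions: list[tuple[str, int, int, str]]
) -> pd.DataFrame:
    """Add genic/intergenic flags and containing-gene names to screen hits.

    A hit is genic iff its position falls inside at least one interval
    (0-based half-open regions against 1-based positions); all overlapping
    interval names are reported, comma-joined.
    """
    genic = []
    genes = []
    for _, row in hits.iterrows():
        names = [
            name
            for chrom, start, end, name in regions
            if chrom == row["chrom"] and locus_in_region(int(row["pos"]), start, end)
        ]
        genic.append(bool(names))
        genes.append(",".join(names))
    out = hits.copy()
    out["genic"] = genic
    out["gene"] = genes
    return out
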