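"""Per-locus and per-sample diversity statistics.

For a biallelic locus with alleles at frequencies p and q = 1 - p:

* gene diversity (Nei's expected heterozygosity) ``GD = 1 - p² - q² = 2pq``,
  maximum 0.5 at p = 0.5;
* polymorphic information content ``PIC = 1 - (p² + q²) - 2p²q²`` (Botstein's
  biallelic form), maximum 0.375 at p = 0.5;
* observed heterozygosity is the fraction of heterozygous calls among
  non-missing calls, per locus or (as a percentage) per sample.

Minor-allele orientation is always fixed by the FULL panel; group-wise
frequencies report the panel-global minor allele's frequency inside the
group, so that cross-group contrasts compare the same allele (a group value
may then legitimately exceed 0.5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


class UndefinedStatisticError(ValueError):
    """A statistic has no value (e.g. all calls missing)."""


def allele_freq(column: np.ndarray) -> float:
    """ALT-allele frequency of one dosage column, over non-missing calls."""
    column = np.asarray(column)
    nonmiss = column != MISSING
    n = int(nonmiss.sum())
    if n == 0:
        raise UndefinedStatisticError("allele frequency undefined: all calls missing")
    return float(column[nonmiss].sum()) / (2 * n)


def alt_freqs(gm: GenotypeMatrix) -> np.ndarray:
    """Vector of per-locus ALT frequencies; NaN where all calls are missing."""
    nonmiss = gm.dosage != MISSING
    n_called = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)


def pic(p):
    """Botstein's biallelic polymorphic information content.

    ``PIC(p) = 1 - (p² + q²) - 2 p² q²``; symmetric in p <-> q, zero for a
    monomorphic locus and maximal (0.375) at p = 0.5.
    """
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(out) if out.ndim == 0 else out


def gene_diversity(p):
    """Nei's gene diversity ``1 - p² - q² = 2pq``; maximal (0.5) at p = 0.5."""
    p = np.asarray(p, dtype=float)
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def observed_het(column: np.ndarray) -> float:
    """Fraction of heterozygous calls at one locus, over non-missing calls."""
    column = np.asarray(column)
    nonmiss = column != MISSING
    n = int(nonmiss.sum())
    if n == 0:
        raise UndefinedStatisticError("observed het undefined: all calls missing")
    return float((column[nonmiss] == 1).sum()) / n


def sample_heterozygosity(row: np.ndarray) -> float:
    """Per-sample heterozygosity as a PERCENT of its non-missing loci."""
    row = np.asarray(row)
    nonmiss = row != MISSING
    n = int(nonmiss.sum())
    if n == 0:
        raise UndefinedStatisticError("sample het undefined: all calls missing")
    return 100.0 * float((row[nonmiss] == 1).sum()) / n


def locus_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus table: call rate, MAF, PIC, gene diversity, observed het."""
    nonmiss = gm.dosage != MISSING
    n_called = nonmiss.sum(axis=0)
    p = alt_freqs(gm)
    maf = np.minimum(p, 1 - p)
    het = np.where(
        n_called > 0,
        np.where(nonmiss, gm.dosage == 1, False).sum(axis=0) / np.maximum(n_called, 1),
        np.nan,
    )
    return pd.DataFrame(
        {
            "chrom": gm.chromosomes(),
            "pos": gm.positions(),
            "id": [loc.id for loc in gm.loci],
            "call_rate": n_called / gm.n_samples,
            "maf": maf,
            "pic": pic(p),  # NaN propagates for all-missing loci
            "gene_diversity": gene_diversity(p),
            "ho": het,
        }
    )


def sample_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample table: non-missing loci, ALT-carrying loci, het percent."""
    nonmiss = gm.dosage != MISSING
    n_nonmiss = nonmiss.sum(axis=1)
    if np.any(n_nonmiss == 0):
        flagged = [s for s, n in zip(gm.samples, n_nonmiss) if n == 0]
        raise UndefinedStatisticError(f"samples with all calls missing: {flagged}")
    n_alt = np.where(nonmiss, gm.dosage > 0, False).sum(axis=1)
    n_het = np.where(nonmiss, gm.dosage == 1, False).sum(axis=1)
    return pd.DataFrame(
        {
            "id": gm.samples,
            "n_nonmissing": n_nonmiss,
            "n_alt_carrying": n_alt,
            "het_percent": 100.0 * n_het / n_nonmiss,
        }
    )


def group_maf(
    gm: GenotypeMatrix, meta: pd.DataFrame, group: str
) -> np.ndarray:
    """Per-locus frequency, within one status group, of the panel-global minor allele.

    Orientation is decided once on the full panel (minor allele = the rarer
    allele over all samples; ties resolve to ALT), then that allele's
    frequency is reported within the group.  Loci where the group has no
    non-missing call are NaN.
    """
    members = set(meta.loc[meta["status"] == group, "id"])
    idx = np.asarray([i for i, s in enumerate(gm.samples) if s in members], dtype=int)
    if idx.size == 0:
        raise ValueError(f"group {group!r} has no samples in the panel")
    p_global = alt_freqs(gm)
    minor_is_alt = p_global <= 0.5  # tie -> ALT

    sub = gm.dosage[idx, :]
    nonmiss = sub != MISSING
    n_called = nonmiss.sum(axis=0)
    alt = np.where(nonmiss, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_grp_alt = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return np.where(minor_is_alt, p_grp_alt, 1.0 - p_grp_alt)
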