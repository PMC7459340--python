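"""Staged SNP quality filters and marker classification.

The filter pipeline mirrors standard reduced-representation QC: a locus
presence filter (the fraction of the panel in which a locus was called,
``r = 0.75`` by default), then a minor-allele-frequency floor (0.05,
inclusive) and a missing-call ceiling (20%), each stage applied to the
survivors of the previous one.  Call rate and percentage of missing values
are complementary; both knobs are exposed because QC reports conventionally
list them separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, Locus


@dataclass
class FilterReport:
    """Per-stage accounting of the filter pipeline."""

    n_input: int
    n_after_presence: int
    n_after_maf: int
    n_after_missingness: int
    dropped_presence: list[str] = field(default_factory=list)
    dropped_maf: list[str] = field(default_factory=list)
    dropped_missingness: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.n_input,
            self.n_after_presence,
            self.n_after_maf,
            self.n_after_missingness,
        )
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"stage counts must be non-increasing: {counts}")


def _locus_call_stats(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(#non-missing calls, ALT-allele frequency over non-missing) per locus."""
    nonmiss = gm.dosage != MISSING
    n_called = nonmiss.sum(axis=0)
    alt_sum = np.where(nonmiss, gm.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt_sum / (2.0 * n_called), np.nan)
    return n_called, p


def presence_filter(gm: GenotypeMatrix, r: float = 0.75) -> GenotypeMatrix:
    """Keep loci called in at least a fraction ``r`` of the samples.

    A locus j survives iff ``(#non-missing at j) / n >= r``.  The sample set
    is unchanged; an empty matrix passes through untouched.
    """
    if not 0 < r <= 1:
        raise ValueError(f"r must be in (0, 1], got {r}")
    if gm.n_loci == 0 or gm.n_samples == 0:
        return gm
    n_called, _ = _locus_call_stats(gm)
    keep = n_called / gm.n_samples >= r
    return gm.take_loci(np.nonzero(keep)[0])


def maf_missing_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.20,
    presence_r: float = 0.75,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Full staged filter: presence → MAF floor → missingness ceiling.

    MAF is computed on non-missing calls only and the threshold is inclusive
    (``>= maf_min``); missingness is ``<= miss_max``.  Each stage operates on
    the survivor set of the previous stage.  Removing everything is legal and
    yields a valid empty matrix plus a complete report.
    """
    for name, v in (("maf_min", maf_min), ("miss_max", miss_max)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")

    n_input = gm.n_loci
    stage1 = presence_filter(gm, presence_r) if gm.n_loci else gm
    kept1 = {loc.id for loc in stage1.loci}
    dropped_presence = [loc.id for loc in gm.loci if loc.id not in kept1]

    if stage1.n_loci:
        n_called, p = _locus_call_stats(stage1)
        maf = np.minimum(p, 1 - p)
        keep_maf = np.where(n_called > 0, maf >= maf_min, False)
    else:
        keep_maf = np.zeros(0, dtype=bool)
    stage2 = stage1.take_loci(np.nonzero(keep_maf)[0])
    dropped_maf = [loc.id for loc, k in zip(stage1.loci, keep_maf) if not k]

    if stage2.n_loci:
        miss_frac = (stage2.dosage == MISSING).mean(axis=0)
        keep_miss = miss_frac <= miss_max
    else:
        keep_miss = np.zeros(0, dtype=bool)
    stage3 = stage2.take_loci(np.nonzero(keep_miss)[0])
    dropped_miss = [loc.id for loc, k in zip(stage2.loci, keep_miss) if not k]

    report = FilterReport(
        n_input=n_input,
        n_after_presence=stage1.n_loci,
        n_after_maf=stage2.n_loci,
        n_after_missingness=stage3.n_loci,
        dropped_presence=dropped_presence,
        dropped_maf=dropped_maf,
        dropped_missingness=dropped_miss,
    )
    return stage3, report


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_substitution(locus: Locus) -> str:
    """Classify a biallelic SNP as ``"transition"`` or ``"transversion"``.

    Transitions are purine<->purine (A/G) or pyrimidine<->pyrimidine (C/T);
    everything else among ACGT pairs is a transversion.
    """
    pair = {locus.ref, locus.alt}
    if not pair <= (_PURINES | _PYRIMIDINES):
        raise ValueError(f"non-ACGT alleles: {locus.ref}/{locus.alt}")
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def ts_tv_counts(gm: GenotypeMatrix) -> tuple[int, int]:
    """(transitions, transversions) tallies over all loci; sums to n_loci."""
    ts = sum(classify_substitution(loc) == "transition" for loc in gm.loci)
    return ts, gm.n_loci - ts


def snp_density(
    gm: GenotypeMatrix, chrom_lengths: dict[str, int] | None = None
) -> "pd.DataFrame":
    """Per-chromosome SNP count and mean inter-SNP distance in kb.

    Mean inter-distance is span / (count - 1): the average gap between
    consecutive SNPs.  Chromosomes with fewer than two loci get NaN distance.
    ``chrom_lengths`` (optional) only adds chromosomes with zero SNPs to the
    table; density is independent of the sample set.
    """
    import pandas as pd

    chroms = gm.chromosomes()
    positions = gm.positions()
    all_chroms = list(dict.fromkeys(chroms.tolist()))
    if chrom_lengths:
        all_chroms += [c for c in chrom_lengths if c not in all_chroms]
    rows = []
    for c in all_chroms:
        pos = positions[chroms == c]
        count = len(pos)
        if count >= 2:
            dist_kb = (pos.max() - pos.min()) / (count - 1) / 1000.0
        else:
            dist_kb = float("nan")
        rows.append({"chrom": c, "n_snps": count, "mean_interdistance_kb": dist_kb})
    return pd.DataFrame(rows)
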