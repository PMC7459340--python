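"""Genotype matrix container and I/O for VCF, metadata tables and region files.

The central object is :class:`GenotypeMatrix`: an accessions x loci matrix of
diploid allele dosages (count of ALT alleles, 0/1/2, with ``MISSING = -1`` for
no-calls) plus the locus coordinates and alleles.  Dosage counts ALT alleles,
never minor alleles — minor-allele orientation is frequency dependent and is
handled downstream by the diversity statistics.

Coordinate conventions: VCF positions are 1-based; BED regions are 0-based
half-open.  A locus at position ``p`` overlaps region ``[s, e)`` iff
``s < p <= e``.  All conversions go through :func:`locus_in_region` so the
off-by-one logic lives in exactly one place.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call in the dosage matrix.
MISSING: int = -1

#: Closed vocabulary of accession biological statuses.
STATUSES = (
    "da_serbo",
    "fresh_landrace",
    "heirloom",
    "cultivar",
    "breeding_line",
    "unknown",
)

_BASES = frozenset("ACGT")


class VcfParseError(ValueError):
    """Raised for malformed VCF input (bad header, non-diploid calls, ...)."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP locus.

    Attributes
    ----------
    chrom : chromosome label.
    pos : 1-based position in bp.
    ref, alt : single-base alleles, distinct, each one of A/C/G/T.
    id : locus identifier string.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"alleles must be single bases in ACGT: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles must differ, both are {self.ref}")


@dataclass
class GenotypeMatrix:
    """Accessions x loci diploid dosage matrix.

    ``dosage[i, j]`` counts ALT alleles of sample ``i`` at locus ``j`` and is
    one of ``{0, 1, 2, MISSING}``.  Loci are kept sorted by (chrom, pos);
    sample IDs are unique.
    """

    samples: list[str]
    loci: list[Locus]
    dosage: np.ndarray  # (n_samples, n_loci), int8

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, L = len(self.samples), len(self.loci)
        if self.dosage.shape != (n, L):
            raise ValueError(f"dosage shape {self.dosage.shape} != ({n}, {L})")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample IDs")
        ok = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.dosage[~ok])
            raise ValueError(f"invalid dosage values {bad.tolist()}")
        keys = [(loc.chrom, loc.pos) for loc in self.loci]
        if keys != sorted(keys):
            idx = sorted(range(L), key=keys.__getitem__)
            self.loci = [self.loci[j] for j in idx]
            self.dosage = self.dosage[:, idx]

    # -- conveniences -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def chromosomes(self) -> np.ndarray:
        return np.asarray([loc.chrom for loc in self.loci])

    def positions(self) -> np.ndarray:
        return np.asarray([loc.pos for loc in self.loci], dtype=np.int64)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask, True where the call is missing."""
        return self.dosage == MISSING

    def take_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[j] for j in index],
            dosage=self.dosage[:, index].copy(),
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            loci=list(self.loci),
            dosage=self.dosage[index, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.dosage, other.dosage)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a diploid multi-sample VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are dropped (counted in the log) when
    ``biallelic_only`` is set.  Phased and unphased separators are treated
    identically; ``./.`` becomes :data:`MISSING`.

    Raises
    ------
    VcfParseError
        On a malformed header or a non-diploid genotype call.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    loci: list[Locus] = []
    cols: list[np.ndarray] = []
    n_dropped = 0
    for rec in vcf:
        alts = rec.ALT
        is_snp = len(rec.REF) == 1 and all(len(a) == 1 for a in alts)
        if biallelic_only and (len(alts) != 1 or not is_snp):
            n_dropped += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise VcfParseError(
                    f"non-diploid GT for sample {samples[i]} at "
                    f"{rec.CHROM}:{rec.POS} (ploidy {len(alleles)})"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING
            else:
                col[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        loci.append(
            Locus(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alts[0],
                  id=rec.ID or ".")
        )
        cols.append(col)
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    dosage = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, loci=loci, dosage=dosage)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write a minimal VCF v4.2 (GT-only FORMAT) such that
    ``read_vcf(write_vcf(gm)) == gm``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radpop\n")
        for chrom in dict.fromkeys(loc.chrom for loc in gm.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, loc in enumerate(gm.loci):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{loc.id}\t{loc.ref}\t{loc.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the accession metadata TSV (columns ``id``, ``status``, ``origin``).

    Unknown status tokens are mapped to ``"unknown"`` with a warning;
    duplicated IDs are an error.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"id", "status", "origin"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    dup = meta["id"][meta["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate accession IDs in metadata: {dup}")
    bad = ~meta["status"].isin(STATUSES)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} accession(s) with unrecognized status mapped to "
            f"'unknown': {sorted(meta.loc[bad, 'status'].unique())}",
            stacklevel=2,
        )
        meta.loc[bad, "status"] = "unknown"
    return meta.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.to_csv(path, sep="\t", index=False)
    return path


def read_regions_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED4 file into (chrom, start, end, name) tuples (0-based half-open)."""
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            out.append((chrom, start, end, name))
    return out


# ---------------------------------------------------------------------------
# Region queries
# ---------------------------------------------------------------------------

def locus_in_region(pos: int, start: int, end: int) -> bool:
    """True iff a 1-based locus position falls in a 0-based half-open region.

    The single place where the BED/VCF coordinate conversion happens:
    position ``p`` (1-based) overlaps ``[start, end)`` (0-based) iff
    ``start < p <= end``.
    """
    return start < pos <= end


def variants_in_regions(
    gm: GenotypeMatrix,
    regions: Iterable[tuple[str, int, int, str]],
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Find loci inside named regions and count minor-allele carriers per group.

    A *carrier* is a sample holding at least one copy of the panel-global
    minor allele at the locus.  When ``meta`` is given, carrier counts are
    broken down by biological status; otherwise a single ``all`` column is
    produced.  Unknown chromosomes simply yield no rows (logged).

    Returns a DataFrame with one row per (region, locus) overlap.
    """
    chroms = gm.chromosomes()
    positions = gm.positions()
    known_chroms = set(chroms.tolist())

    if meta is not None:
        meta_idx = {s: i for i, s in enumerate(gm.samples)}
        groups = {
            status: np.asarray([meta_idx[s] for s in sub["id"] if s in meta_idx], dtype=int)
            for status, sub in meta.groupby("status")
        }
    else:
        groups = {"all": np.arange(gm.n_samples)}

    rows = []
    for chrom, start, end, name in regions:
        if chrom not in known_chroms:
            logger.info("variants_in_regions: chromosome %r not in panel", chrom)
            continue
        hit = np.nonzero(
            (chroms == chrom) & (start < positions) & (positions <= end)
        )[0]
        for j in hit:
            col = gm.dosage[:, j]
            nonmiss = col != MISSING
            n_alleles = 2 * int(nonmiss.sum())
            if n_alleles == 0:
                continue
            p_alt = float(col[nonmiss].sum()) / n_alleles
            # carrier of the panel-global minor allele
            if p_alt <= 0.5:
                carrier = (col > 0) & nonmiss
            else:
                carrier = (col < 2) & nonmiss
            row = {
                "region": name,
                "chrom": chrom,
                "pos": int(positions[j]),
                "locus_id": gm.loci[j].id,
                "alt_freq": p_alt,
            }
            for gname, gidx in groups.items():
                row[f"carriers_{gname}"] = int(carrier[gidx].sum())
            rows.append(row)
    cols = ["region", "chrom", "pos", "locus_id", "alt_freq"] + [
        f"carriers_{g}" for g in groups
    ]
    return pd.DataFrame(rows, columns=cols)
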