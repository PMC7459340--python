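"""Structured synthetic genotype panels with known truth.

Emulates, at desk scale, a tomato germplasm panel of the kind produced by
ddRAD genotyping: K diverged subpopulations with occasional admixture, high
homozygosity (selfing crop), minor-allele spectra surviving a 0.05 MAF floor,
distance-dependent linkage disequilibrium decaying within a few kb, a labeled
long-shelf-life ('da serbo') group carrying planted contrasting-frequency
loci, and planted near-duplicate accessions.

Model
-----
Ancestral allele frequencies ``p_j ~ Uniform(0.05, 0.95)`` diverge into K
population frequencies under the Balding–Nichols model::

    f_kj ~ Beta(p_j (1-F_k)/F_k,  (1-p_j)(1-F_k)/F_k)

so that E[f_kj] = p_j and Var[f_kj] = F_k p_j (1-p_j).  Per population,
``n_founders`` founder haplotypes are drawn Bernoulli(f_kj) per locus; each
sample haplotype is a founder *mosaic*: it copies one founder and switches to
a freshly drawn founder between adjacent loci with probability
``1 - exp(-switch_rate_per_bp * gap_bp)``.  Shared founder segments make
nearby loci correlated, which induces r² decay on the 1/switch_rate length
scale.  Admixed samples re-draw the population at every switch point
according to their Dirichlet(alpha) membership row.

Selfing is modeled by a per-locus identity-by-descent mask: with probability
``inbreeding`` a locus is homozygous for the first haplotype's allele,
otherwise the genotype is the sum of the two independent haplotypes.  This
reproduces the 2–5% per-sample heterozygosity regime typical of cultivated
tomato while preserving the mosaic LD structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, Locus

_BASES = np.array(list("ACGT"))

#: Panel composition mirrored from a 288-accession germplasm collection:
#: 77 'da serbo' landraces, 75 fresh-consumption landraces, 46 heirlooms,
#: 76 cultivars, 14 breeding lines.
STATUS_COMPOSITION = {
    "da_serbo": 77 / 288,
    "fresh_landrace": 75 / 288,
    "heirloom": 46 / 288,
    "cultivar": 76 / 288,
    "breeding_line": 14 / 288,
}

_STATUS_PREFIX = {
    "da_serbo": "DS",
    "fresh_landrace": "FC",
    "heirloom": "HL",
    "cultivar": "CL",
    "breeding_line": "BL",
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel generator.

    Defaults describe a 288-accession, K=6 panel with Balding–Nichols
    divergence F=0.3, strong selfing (inbreeding 0.9, giving ~2–3% mean
    per-sample heterozygosity), 2% missing calls, and LD decaying on a
    ~2 kb scale (switch_rate_per_bp = 5e-4).
    """

    K: int = 6
    n_per_pop: int = 48
    L: int = 2000
    F_k: float | tuple[float, ...] = 0.3
    alpha: float = 0.2
    admixed_fraction: float = 0.1
    inbreeding: float = 0.9
    missing_rate: float = 0.02
    n_founders: int = 8
    switch_rate_per_bp: float = 5e-4
    chrom_lengths: tuple[int, ...] = tuple([500_000] * 12)
    n_private: int = 20
    n_duplicates: int = 2
    seed: int = 0

    def f_values(self) -> np.ndarray:
        F = np.broadcast_to(np.asarray(self.F_k, dtype=float), (self.K,)).copy()
        return F

    def validate(self) -> None:
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        F = self.f_values()
        if np.any(F <= 0) or np.any(F >= 1):
            raise ConfigError("F_k must lie in the open interval (0, 1)")
        for name in ("admixed_fraction", "inbreeding", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if not 0 <= self.n_private <= self.L:
            raise ConfigError("n_private must be in [0, L]")
        if self.alpha <= 0 or self.switch_rate_per_bp < 0:
            raise ConfigError("alpha must be > 0 and switch_rate_per_bp >= 0")
        if self.n_founders < 1 or self.n_per_pop < 1 or self.L < 1:
            raise ConfigError("n_founders, n_per_pop and L must be >= 1")
        if 2 * self.n_duplicates > self.K * self.n_per_pop:
            raise ConfigError("too many duplicate pairs for the panel size")

    @property
    def n_samples(self) -> int:
        return self.K * self.n_per_pop


@dataclass
class SimTruth:
    """Ground truth of a simulated panel."""

    Q_true: np.ndarray  # (n, K) admixture proportions, rows sum to 1
    pop_labels: np.ndarray  # (n,) dominant population index
    group_labels: np.ndarray  # (n,) 'da_serbo' vs 'other'
    private_locus_indices: np.ndarray  # (n_private,)
    duplicate_pairs: list[tuple[int, int]]  # (source, copy) sample indices
    founder_haplotypes: dict[int, np.ndarray]  # pop -> (n_founders, L)


def simulate_frequencies(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ancestral frequencies and Balding–Nichols population frequencies.

    Returns ``(p, f)`` with ``p`` of shape (L,) and ``f`` of shape (K, L),
    every ``f_kj`` clamped to [1e-6, 1-1e-6].
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(0.05, 0.95, size=cfg.L)
    F = cfg.f_values()
    a = p[None, :] * ((1 - F) / F)[:, None]
    b = (1 - p)[None, :] * ((1 - F) / F)[:, None]
    f = rng.beta(a, b)
    return p, np.clip(f, 1e-6, 1 - 1e-6)


def replace_cfg_F(cfg: SimulationConfig, F_new: tuple[float, ...]) -> SimulationConfig:
    from dataclasses import replace

    return replace(cfg, F_k=F_new)


def _draw_positions(cfg: SimulationConfig, rng: np.random.Generator) -> list[Locus]:
    """Place L loci uniformly over the configured chromosomes, sorted."""
    lengths = np.asarray(cfg.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()
    counts = rng.multinomial(cfg.L, probs)
    # guarantee uniqueness of positions within a chromosome
    loci: list[Locus] = []
    j = 0
    for c, (cnt, clen) in enumerate(zip(counts, lengths)):
        if cnt == 0:
            continue
        pos = np.sort(rng.choice(int(clen), size=cnt, replace=False)) + 1
        for p in pos:
            ref_i = rng.integers(4)
            alt_i = (ref_i + 1 + rng.integers(3)) % 4
            loci.append(
                Locus(
                    chrom=f"chr{c + 1:02d}",
                    pos=int(p),
                    ref=str(_BASES[ref_i]),
                    alt=str(_BASES[alt_i]),
                    id=f"snp{j:05d}",
                )
            )
            j += 1
    return loci


def _mosaic_haplotype(
    q_row: np.ndarray,
    founders: dict[int, np.ndarray],
    n_founders: int,
    switch_prob: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One haplotype as a founder mosaic along the genome.

    ``switch_prob[j]`` is the probability of re-drawing (population, founder)
    between locus j-1 and locus j; it is 1 at chromosome starts.
    """
    L = switch_prob.shape[0]
    switches = rng.random(L) < switch_prob
    switches[0] = True
    seg_id = np.cumsum(switches) - 1
    n_seg = seg_id[-1] + 1
    seg_pop = rng.choice(len(q_row), size=n_seg, p=q_row)
    seg_founder = rng.integers(n_founders, size=n_seg)
    hap = np.empty(L, dtype=np.int8)
    # gather founder alleles segment-wise
    pop_per_locus = seg_pop[seg_id]
    founder_per_locus = seg_founder[seg_id]
    for k in np.unique(pop_per_locus):
        mask = pop_per_locus == k
        hap[mask] = founders[int(k)][founder_per_locus[mask], np.nonzero(mask)[0]]
    return hap


def _assign_statuses(n: int) -> np.ndarray:
    """Deterministic status assignment mirroring the germplasm composition."""
    counts = {s: int(round(frac * n)) for s, frac in STATUS_COMPOSITION.items()}
    # fix rounding drift on the largest class
    drift = n - sum(counts.values())
    counts["da_serbo"] += drift
    statuses = []
    for s, c in counts.items():
        statuses.extend([s] * c)
    return np.asarray(statuses[:n])


def simulate_panel(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Simulate a full structured panel; fully reproducible from ``cfg.seed``.

    Returns the genotype matrix, an accession metadata table (id, status,
    origin) and the :class:`SimTruth` ground truth.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, K, L = cfg.n_samples, cfg.K, cfg.L

    loci = _draw_positions(cfg, rng)
    chroms = np.asarray([loc.chrom for loc in loci])
    positions = np.asarray([loc.pos for loc in loci], dtype=np.int64)

    # The finite founder pool adds drift on top of the Beta divergence:
    # Var(pool freq) = F' p q + (1 - F') p q / n_founders.  Shrink the Beta
    # parameter so the REALIZED population divergence equals the requested
    # F_k: F' = (F - 1/n_f) / (1 - 1/n_f).  Requires F_k > 1/n_founders.
    F_req = cfg.f_values()
    inv_nf = 1.0 / cfg.n_founders
    if np.any(F_req <= inv_nf):
        raise ConfigError(
            f"F_k must exceed 1/n_founders = {inv_nf:.3g}; founder-pool drift "
            "alone already produces that much divergence"
        )
    cfg_adj = replace_cfg_F(cfg, tuple((F_req - inv_nf) / (1.0 - inv_nf)))
    _, f = simulate_frequencies(cfg_adj, rng)
    founders = {
        k: (rng.random((cfg.n_founders, L)) < f[k]).astype(np.int8) for k in range(K)
    }

    # per-locus switch probability from the bp gap to the previous locus
    gaps = np.diff(positions, prepend=positions[0])
    new_chrom = np.empty(L, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    switch_prob = 1.0 - np.exp(-cfg.switch_rate_per_bp * np.maximum(gaps, 0))
    switch_prob[new_chrom] = 1.0

    # membership rows
    Q = np.zeros((n, K))
    pop_labels = np.repeat(np.arange(K), cfg.n_per_pop)
    Q[np.arange(n), pop_labels] = 1.0
    n_admixed = int(round(cfg.admixed_fraction * n))
    admixed_idx = rng.choice(n, size=n_admixed, replace=False) if n_admixed else np.array([], dtype=int)
    if n_admixed:
        Q[admixed_idx] = rng.dirichlet(np.full(K, cfg.alpha), size=n_admixed)
        pop_labels = pop_labels.copy()
        pop_labels[admixed_idx] = np.argmax(Q[admixed_idx], axis=1)

    hap1 = np.empty((n, L), dtype=np.int8)
    hap2 = np.empty((n, L), dtype=np.int8)
    for i in range(n):
        hap1[i] = _mosaic_haplotype(Q[i], founders, cfg.n_founders, switch_prob, rng)
        hap2[i] = _mosaic_haplotype(Q[i], founders, cfg.n_founders, switch_prob, rng)

    statuses = _assign_statuses(n)
    group_labels = np.where(statuses == "da_serbo", "da_serbo", "other")
    focus = group_labels == "da_serbo"

    # planted contrasting-frequency loci: ALT common in the focus group,
    # rare elsewhere, regardless of population structure
    private_idx = (
        np.sort(rng.choice(L, size=cfg.n_private, replace=False))
        if cfg.n_private
        else np.array([], dtype=int)
    )
    for j in private_idx:
        hap1[focus, j] = rng.random(focus.sum()) < 0.55
        hap2[focus, j] = rng.random(focus.sum()) < 0.55
        hap1[~focus, j] = rng.random((~focus).sum()) < 0.02
        hap2[~focus, j] = rng.random((~focus).sum()) < 0.02

    # selfing: per-locus IBD mask makes most loci homozygous for hap1
    ibd = rng.random((n, L)) < cfg.inbreeding
    dosage = np.where(ibd, 2 * hap1, hap1 + hap2).astype(np.int8)

    # planted near-duplicates: overwrite the second member of each pair with
    # a noisy copy of the first (per-locus flip probability 1e-3)
    duplicate_pairs: list[tuple[int, int]] = []
    if cfg.n_duplicates:
        chosen = rng.choice(n, size=2 * cfg.n_duplicates, replace=False)
        for a, b in zip(chosen[::2], chosen[1::2]):
            copy = dosage[a].copy()
            flips = np.nonzero(rng.random(L) < 1e-3)[0]
            for j in flips:
                others = [v for v in (0, 1, 2) if v != copy[j]]
                copy[j] = others[rng.integers(2)]
            dosage[b] = copy
            Q[b] = Q[a]
            pop_labels[b] = pop_labels[a]
            duplicate_pairs.append((int(a), int(b)))

    if cfg.missing_rate:
        miss = rng.random((n, L)) < cfg.missing_rate
        dosage[miss] = MISSING

    counters: dict[str, int] = {}
    ids = []
    for s in statuses:
        counters[s] = counters.get(s, 0) + 1
        ids.append(f"{_STATUS_PREFIX[s]}{counters[s]}")
    origins = np.where(focus, "Italy", "various")
    meta = pd.DataFrame({"id": ids, "status": statuses, "origin": origins})

    gm = GenotypeMatrix(samples=ids, loci=loci, dosage=dosage)
    truth = SimTruth(
        Q_true=Q,
        pop_labels=pop_labels,
        group_labels=group_labels,
        private_locus_indices=private_idx,
        duplicate_pairs=duplicate_pairs,
        founder_haplotypes=founders,
    )
    return gm, meta, truth


# ---------------------------------------------------------------------------
# Truth export / import
# ---------------------------------------------------------------------------

def export_truth(truth: SimTruth, directory: str | Path) -> dict[str, Path]:
    """Write ground truth as plain whitespace/TSV tables; lossless round-trip."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "Q_true": directory / "Q_true.txt",
        "labels": directory / "labels.tsv",
        "private": directory / "private_loci.txt",
        "duplicates": directory / "duplicate_pairs.txt",
    }
    np.savetxt(paths["Q_true"], truth.Q_true, fmt="%.17g")
    pd.DataFrame(
        {"pop": truth.pop_labels, "group": truth.group_labels}
    ).to_csv(paths["labels"], sep="\t", index=False)
    np.savetxt(paths["private"], truth.private_locus_indices, fmt="%d")
    np.savetxt(paths["duplicates"], np.asarray(truth.duplicate_pairs, dtype=int).reshape(-1, 2), fmt="%d")
    return paths


def load_truth(directory: str | Path) -> SimTruth:
    """Read back what :func:`export_truth` wrote (founder haplotypes excluded)."""
    directory = Path(directory)
    Q = np.atleast_2d(np.loadtxt(directory / "Q_true.txt"))
    labels = pd.read_csv(directory / "labels.tsv", sep="\t")
    private = np.atleast_1d(np.loadtxt(directory / "private_loci.txt", dtype=int))
    dup = np.atleast_2d(np.loadtxt(directory / "duplicate_pairs.txt", dtype=int))
    pairs = [tuple(map(int, row)) for row in dup] if dup.size else []
    return SimTruth(
        Q_true=Q,
        pop_labels=labels["pop"].to_numpy(),
        group_labels=labels["group"].to_numpy(),
        private_locus_indices=private,
        duplicate_pairs=pairs,
        founder_haplotypes={},
    )
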