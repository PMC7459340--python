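# Methods

`radpop` implements the statistical pipeline used to characterize the genomic
diversity of a cultivated-tomato germplasm panel genotyped by ddRAD
sequencing: SNP quality filtering, locus/sample diversity statistics,
model-based ancestry with cross-validated choice of the number of clusters,
allele-sharing distance clustering and principal-coordinate ordination,
linkage-disequilibrium decay, a group-private allele screen, redundancy
detection and mini-core selection.  Because the raw sequencing data are not
needed to validate the statistics, the package ships a synthetic panel
generator with full ground truth, and every stage is validated end to end
against that truth or against independent brute-force oracles.

## Genotype representation

Genotypes are diploid ALT-allele dosages in {0, 1, 2} with a `-1` sentinel
for missing calls, held in an accessions × loci `int8` matrix together with
locus coordinates and alleles (`genotype_io.GenotypeMatrix`).  Dosage counts
ALT alleles, never minor alleles: minor-allele orientation depends on
frequencies and is applied downstream (see the contrast screen).  VCF
positions are 1-based and BED regions 0-based half-open; a locus at position
p overlaps [s, e) iff s < p ≤ e, and this conversion lives in a single
function (`locus_in_region`) because a silent off-by-one at either boundary
is the classic failure mode.  Multi-allelic and indel records are dropped on
read rather than split — every statistic in the pipeline is defined for
biallelic SNPs.

## The synthetic panel generator

The generator (`synthetic_panel`) emulates the features of a
reduced-representation tomato panel that the downstream methods are
sensitive to; its defaults describe a 288-accession collection split across
77 'da serbo' (long-shelf-life) landraces, 75 fresh-consumption landraces,
46 heirlooms, 76 cultivars and 14 breeding lines.

**Population frequencies.** Ancestral frequencies p_j ~ Uniform(0.05, 0.95)
diverge into K = 6 populations under the Balding–Nichols model,
f_kj ~ Beta(p_j(1−F)/F, (1−p_j)(1−F)/F), so E[f] = p and
Var[f] = F·p(1−p).  Default F = 0.3 per population.

**Founder mosaics and LD.** Each population has a pool of `n_founders = 8`
founder haplotypes drawn Bernoulli(f_kj).  A sample haplotype copies one
founder and re-draws (population, founder) between adjacent loci with
probability 1 − exp(−r·d) for gap d bp (`switch_rate_per_bp` r = 5·10⁻⁴,
i.e. a ~2 kb segment scale).  Shared founder segments make nearby loci
correlated, which produces r² decaying with distance on the 1/r scale — the
only LD property the pipeline consumes.  A coalescent simulator would add
realism (recombination-graph genealogies, mutation-age structure) that none
of the tested statistics use.

**Founder-drift compensation.** The finite founder pool itself adds drift:
the pool frequency has variance F′·pq + (1−F′)·pq/n_f when the Beta uses
F′.  Drawing founders directly at the requested F therefore yields a
*realized* divergence of about F + (1−F)/n_f (≈ 0.3 when 0.2 is requested
with 8 founders).  The generator instead shrinks the Beta parameter to
F′ = (F − 1/n_f)/(1 − 1/n_f), so the realized population divergence — what
an F_ST estimator sees — equals the requested F.  Consequently F must
exceed 1/n_founders; smaller targets are rejected with a `ConfigError`
rather than silently missed.

**Selfing.** Cultivated tomato is highly autogamous; panels show ~2–5%
per-sample heterozygosity, not the ~25% a random-mating diploid would give
at these frequencies.  The generator draws two independent haplotypes and
then, per locus, makes the genotype homozygous for the first haplotype's
allele with probability `inbreeding` (default 0.9, giving ≈2.6% mean
heterozygosity).  The per-locus (rather than per-sample) mask keeps every
sample in the 2–4% band instead of producing a bimodal mixture, and leaves
the haplotype-level LD structure intact.

**Planted structure.** `n_private = 20` loci are re-drawn group-conditionally
— 'da serbo' haplotype alleles Bernoulli(0.55), all others Bernoulli(0.02) —
which satisfies the screen's >0.4 / <0.1 contrast in ≥90% of plantings once
the focus group has ≥30 members (binomial tail calculation, checked by
simulation).  `n_duplicates = 2` accession pairs are planted by overwriting
one member with a copy of the other whose dosages flip with probability
10⁻³ per locus.  Missing calls are MCAR (default 2%), applied last; the
quality filters address missingness *rates*, so no mechanism beyond MCAR is
modeled.  All randomness flows from one `numpy` generator seeded by
`SimulationConfig.seed`; the same config is byte-identical across runs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genotyping error and allelic dropout, depth-
dependent missingness, the transition/transversion bias of real mutation
spectra (synthetic REF/ALT pairs are uniform over ordered base pairs, so
Ts/Tv ≈ 0.5 by construction), linkage between the planted contrast loci and
background structure, and any phenotype.

## Filters and diversity statistics

Filtering proceeds in the order presence → MAF → missingness, each stage on
the survivors of the previous one: a locus must be called in ≥75% of
samples (`r = 0.75`), have minor-allele frequency ≥0.05 (inclusive — the
usual tooling convention; the boundary is tested), and ≤20% missing calls.
MAF is always computed on non-missing calls.  The staged pipeline is
idempotent and is tested against an independent per-locus re-check on
random matrices.

Per-locus statistics use the standard biallelic forms: Nei gene diversity
GD = 2pq (maximum 0.5 at p = 0.5) and Botstein polymorphic information
content PIC = 1 − (p² + q²) − 2p²q² (maximum 0.375 at p = 0.5).  The two
are sometimes conflated in germplasm reports ("0.0 to 0.5" is true only of
GD); both are implemented with their correct analytic ranges and the
package's observed PIC maximum of 0.375 confirms the Botstein form.
Per-chromosome SNP density reports span/(count−1), the mean gap between
consecutive SNPs; chromosomes with fewer than two loci have undefined
density.

Group-wise allele frequencies fix the minor allele **once, on the full
panel** (ties orient to ALT), then report that allele's frequency inside
each group.  Re-orienting per group would make a cross-group contrast
compare different alleles; the price is that a group frequency can exceed
0.5, which is intended.

## Ancestry model

The admixture likelihood treats each genotype as
g_ij ~ Binomial(2, Σ_k q_ik f_kj) over non-missing entries.  Fitting is by
EM with allele-level responsibilities; the block updates collapse to four
matrix products per iteration, preserve the row-simplex constraint on Q
algebraically, and increase the log-likelihood monotonically (asserted in
tests at every iteration).  EM reaches the same stationary points as the
quasi-Newton block relaxation used by dedicated ancestry software but its
monotonicity is trivially verifiable, which is worth more here than
convergence speed.  Defaults: tolerance |Δℓ| < 10⁻⁴, ≤2000 iterations,
best of 3 random restarts, clusters reported ordered by total membership.
F is clamped to [10⁻⁶, 1−10⁻⁶] throughout.

K is chosen by entry-masking cross-validation: non-missing genotype
*entries* (not samples) are partitioned into 10 random folds; each fold is
hidden in turn, the model refitted, and the held-out entries scored by mean
binomial deviance −[g ln π̂ + (2−g) ln(1−π̂)]/2.  The CV refits use a
looser EM tolerance (10⁻², ≤400 iterations): the deviance gaps that
separate candidate K values (~0.02 on simulated panels) are two orders of
magnitude above the fit-to-fit noise at that tolerance, and the selected K
is unchanged against the strict setting.

Samples are classified to their argmax cluster when max_k q_ik ≥ 0.5 and
"admixed" otherwise (exact ties are admixed).  Between-cluster F_ST is the
Hudson-type ratio of sums on the *inferred* frequencies,
Σ(f_k−f_l)² / Σ[f_k(1−f_l)+f_l(1−f_k)], without a sampling correction —
the frequencies are model parameters, not finite-sample estimates.  A
separate empirical Hudson estimator (with the usual −pq/(n−1) correction,
ratio of averages) is provided for genotype groups and is the one validated
against the generative divergence.  An optional bootstrap-over-loci routine
returns per-entry standard errors of Q; it is off by default because it
refits the model per replicate.

## Distances, clustering, ordination

The dissimilarity index between accessions is the proportion of unmatching
alleles averaged over co-non-missing loci, |g_a − g_b|/2 per locus (0, ½ or
1).  This equals 1 minus the allele-sharing proportion; "allele-sharing
distance" and "dissimilarity index" are the same quantity.  Identical
genotypes give exactly 0.0, which is the redundancy criterion; a scan
reports all pairs under a threshold (default 0.005) in ascending order.
Pairs with no shared locus are an error unless explicitly allowed.

The dendrogram uses Ward linkage in the Ward.D2 convention (scipy's
`linkage(..., "ward")` on the condensed distance matrix); heights are
non-decreasing and trees are isomorphic under sample permutation.  Classical
MDS is principal-coordinates analysis: double-center −½·J·D²·J,
eigendecompose, scale eigenvectors by √λ for the positive eigenvalues;
negative eigenvalues (the dissimilarity is not exactly Euclidean) are
reported but never used, and each axis is sign-fixed by making its
largest-magnitude loading positive.  On Euclidean inputs the embedding
reproduces all pairwise distances to 10⁻⁸, and coordinates agree with
scikit-bio's independent PCoA implementation up to per-axis sign.

k-means (k-means++/Lloyd, best of restarts, fixed seed) runs on the top-10
principal coordinates, and k is selected by the classification-likelihood
BIC of a shared-variance spherical Gaussian mixture:

    σ² = WSS/(nd),
    ℓ  = Σ_c n_c ln(n_c/n) − (nd/2)·ln(2πσ²) − nd/2,
    BIC = −2ℓ + (kd + k)·ln n.

The mixing-entropy term Σ n_c ln(n_c/n) matters: a criterion built only on
n·d·ln(WSS/(nd)) keeps rewarding subdivision of a single Gaussian (the
log-WSS gain from splitting one blob always beats a k·d·ln n penalty in low
dimension) and therefore cannot recover k = 2 on two clean blobs.  With the
entropy term the two-blob case selects k = 2 and duplicated datasets select
the same k.

## LD

r² is the squared Pearson correlation of dosages over samples called at
both loci (composite LD).  In material this homozygous the composite and
haplotype-phase estimators coincide for practical purposes, and the
composite form needs no phasing and is deterministic.  r² is invariant to
REF/ALT swaps of either locus; pairs monomorphic on the shared subset are
undefined and excluded.  Decay curves bin all intra-chromosomal pairs
within a maximum distance (analysis default 50 kb, 2 kb bins on the
synthetic panel's 500 kb chromosomes); the **half-decay distance** is the
smallest bin midpoint where the mean r² falls to halfway between the
maximum bin mean and the far-field level (mean of the last decile of
non-empty bins).  This is the package's own operationalization of "LD
decays within a few kb" — it is compared qualitatively, never numerically,
to published curves.  For independent loci the expected background is
E[r²] ≈ 1/n, which the unlinked simulation reproduces.

Pruning slides a window (50 SNPs, step 5) along each chromosome; while any
in-window pair exceeds r² = 0.2 the lower-MAF member is removed (tie: the
higher index).  Because removals shift window contents, a single sweep is
not a fixed point; the sweep is repeated until no locus is removed, which
makes the operation idempotent by construction.

## Private-allele screen

For a focus group (default 'da serbo') the screen reports loci with group
MAF > 0.4 in the focus group and < 0.2 in the complement, with a
"most contrasting" tier at < 0.1 — strict inequalities, exactly as printed
thresholds are conventionally applied, and boundary behavior is tested.
Both frequencies refer to the panel-global minor allele (see above).  The
screen is a descriptive threshold rule, not a hypothesis test; no
multiple-testing correction applies, though an optional Fisher-exact column
is available for triage.  Hits can be annotated genic/intergenic against
gene intervals, reporting all containing intervals when they nest.

## Mini-core selection

The core of size round(0.2·n) maximizes the entry-to-nearest-entry
criterion E-NE(S) = mean_{s∈S} min_{t∈S∖{s}} d(s,t) — the canonical spread
measure for core collections; mean entry-to-entry is available behind a
flag.  The optimizer is steepest-ascent swap local search (the single best
in/out exchange per step, strictly improving, hence terminating) restarted
from random subsets.  On random instances with n ≤ 12 it attains the
exhaustively enumerated optimum in ≥95% of cases and always beats the mean
of 1,000 random same-size subsets, which bounds how much the heuristic can
be leaving on the table at panel scale.

## Problem sizes and numerical choices

Validation uses desk-scale panels chosen to make each property measurable:
K recovery at n = 90, L = 1000 (K = 3) and model selection at n = 120,
L = 1500 (K = 6, 10-fold CV over K ∈ 1..8); F_ST recovery at 2 × 100
samples, L = 5000; LD regimes at n = 100 with 400–500 loci on single
chromosomes; filter and screen oracles on 20×100 and 2000-locus matrices.
Degenerate inputs are defined, not crashed: empty matrices pass filters,
all-missing columns raise a typed `UndefinedStatisticError`, monomorphic
pairs give NA r², K = 1 returns the analytic optimum, and tie-breaks
(membership ties → admixed, MAF ties in pruning → higher index, minor-allele
ties → ALT) are deterministic and documented where they occur.

## Known limitations

The generator's founder-mosaic LD has no mutation/genealogy structure, so
LD curves are only qualitatively tomato-like; the admixture model assumes
Hardy–Weinberg within clusters while the panel is strongly selfing, which
leaves Q recovery intact on tested conditions but biases the binomial
deviance scale (harmless for ranking K); the contrast screen inherits the
sampling noise of small groups and its thresholds are descriptive; and the
swap local search carries no global-optimality guarantee beyond the
small-instance oracle and random-baseline checks.
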