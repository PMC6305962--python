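# Methods

This note documents the models, estimators and numerical conventions behind
`sweepscan`, the design choices made where several reasonable options
existed, and what the bundled synthetic cohorts do and do not emulate.

## Quality control

QC runs in a fixed order: (1) drop SNPs unmapped to a chromosome, (2) drop
SNPs with call rate < 0.90, (3) drop samples with missingness > 0.10,
(4) recompute allele frequencies on the retained samples and drop SNPs with
MAF < 0.05. The order matters — MAF is only meaningful on the cohort that
survives — and is recorded in the `QcReport` together with a single primary
reason per dropped item. All three boundaries are strict, following the
thresholds' "less than / more than" phrasing. Coordinates are 1-based
inclusive bp throughout (VCF/PLINK convention); BED input is converted from
0-based half-open on read.

Dataset merging matches SNPs by identifier, not position. Allele
orientation is harmonized by swapping ref/alt (calls flipped `c → 2−c`)
when the pairs are reversed; A/T and C/G SNPs with mismatched alleles are
excluded rather than strand-flipped, because array manifests rarely travel
with reliable strand metadata. Any other incompatible allele pair is also
excluded and reported.

## Diversity and inbreeding

Observed heterozygosity is `(N − O)/N` per individual over non-missing
genotypes. The inbreeding coefficient inverts the expected-homozygosity
identity `P(hom) = f + (1 − f)(p² + q²)` at the moment level:
`F̂ = (O − E)/(N − E)` with
`E = Σ_j [1 − 2 p_j q_j · 2n_j/(2n_j − 1)]`, i.e. the method-of-moments
estimator with the small-sample correction used by standard genotype QC
tools. On a simulated cohort with true within-individual IBD probability
0.25 at 10,000 SNPs the mean `F̂` lands within 0.03 of truth (asserted in
the tests).

LD pruning follows the sliding-window recipe (window 50 SNPs, step 5,
r² > 0.3): within each window, while any retained pair exceeds the
threshold, the lower-MAF member of the worst pair is removed (ties → later
map position) — a deterministic variant of the usual greedy rule. MAF bins
are right-closed: `[0, 0.1], (0.1, 0.2], …, (0.4, 0.5]`, so a MAF of
exactly 0.1 falls in the first bin.

## Kinship, PCA, admixture

Kinship is the KING-robust within-family estimator; "unrelated" uses the
3rd-degree cutoff 0.0884 with greedy removal of the highest-degree sample
(ties → later sample id), which is deterministic and verified against an
exhaustive pair check. PCA standardizes genotypes by `2p̂` and
`√(2p̂(1−p̂))`, mean-imputes missing entries after centering, fits the SVD
on the unrelated subset and projects relatives onto the loadings — a
desk-scale stand-in for partition-based structure-aware PCA.

Global ancestry proportions are estimated per individual by supervised
maximum likelihood against fixed source-panel allele frequencies
(pseudocount-smoothed), maximizing
`Σ_j [g_j log(Σ_k q_k f_kj) + (2−g_j) log(Σ_k q_k (1−f_kj))]` over the
simplex by EM from a uniform start. The log-likelihood is non-decreasing by
construction (asserted); non-convergence within `max_iter` flags the sample
rather than failing. When all source frequency rows coincide, the
likelihood is flat and the result is flagged non-identifiable.

**What "truth" means for recovery.** The generator records both the
Dirichlet-sampled stationary proportions that drive each individual's
ancestry chains and the *realized* fraction of each source along the
simulated genome. With ~10 tracts per haplotype the realized fraction
deviates from the stationary draw by an SD of ~0.1 regardless of marker
count, and any genotype-based estimator targets the realized genome, so
recovery (RMSE ≤ 0.05 at 10,000 SNPs) is measured against `realized_q`.

## Haplotype scans

EHH from a core SNP to a marker is the probability that two random carrier
haplotypes are identical over the inclusive interval:
`Σ_h C(n_h,2) / C(n_c,2)` over distinct extended haplotypes. iHH
integrates the decay curve over physical position by the trapezoid rule,
separately left and right, stopping at the linearly interpolated point
where EHH crosses the 0.05 cutoff. Walks that reach a chromosome end or
cross a gap > 200 kb before the cutoff flag the SNP, and flagged SNPs are
excluded rather than integrated to the boundary. Integration is over bp (no
genetic map was assumed); a constant-rate cM conversion is available but
off by default.

iHS is `ln(iHH_ancestral / iHH_derived)` — strongly negative values mark
extended homozygosity on the derived allele — standardized within 20
equal-width derived-allele-frequency bins (bins with fewer than 2 SNPs are
merged into the nearest occupied neighbour). Ancestral alleles are the
majority allele over the full dataset, ties resolving to the reference
allele; monomorphic SNPs are unusable for iHS. The display transform
`−log₁₀[1 − 2|Φ(iHS) − 0.5|]` equals `−log₁₀` of the two-sided Gaussian
p-value.

XP-EHH compares all haplotypes of an object population against a reference
at each focal SNP (EHH is unconditional on the core allele). Both
populations are integrated over the same interval, truncated where the
EHH of the pooled haplotypes crosses the cutoff, and
`ln(iHH_obj / iHH_ref)` is standardized genome-wide (not per chromosome) to
exactly zero mean and unit variance. Relabelling the populations negates
the raw score exactly.

The decay walks are numba kernels; class labels are re-compressed at each
step (sort + run-length), so EHH is exact pair counting, verified against a
brute-force enumeration oracle on small fixtures.

## PCA outlier scan

Each SNP's standardized genotype vector is regressed on K centered PC score
vectors; `z_k = β_k / se(β_k)` with residual df `n − K`. The Mahalanobis
distance uses the sample mean and covariance of the z-vectors by default; a
robust option (coordinate-wise median, MAD-scaled covariance) is available
and recorded in the output metadata. p-values are upper-tail chi-square
with an explicit `df` parameter defaulting to K — published calibrations
sometimes reflect fewer effective dimensions than retained components, so
df is not hard-wired to K. An optional genomic-inflation rescaling
(`D²/λ`, λ = median ratio) is off by default.

Cattell's scree rule is inherently graphical; it is operationalized as
K = 1 + the largest k whose drop `(v_k − v_{k+1})/(v_1 − v_last)` exceeds
0.1 ("the component after the last big drop"), with K = 1 for flat
profiles. On a scree of (0.46, 0.13, 0.05, 0.049, …) this yields K = 3.

## Regions

FDR control is Benjamini–Hochberg step-up at α = 0.01 by default (Storey
q-values with the λ = 0.5 π₀ estimate are optional); the realized p-value
cutoff is reported so users can compare it with published thresholds.
Candidate sweep regions are maximal chains of significant SNPs with
consecutive gaps ≤ 500 kb (inclusive, reading "not more than" as ≤) and at
least two members; singletons are reported separately. Each region's top
SNP is the member with the most extreme absolute statistic, ties going to
the smallest position. Gene annotation intersects closed intervals against
`[start − 100 kb, end + 100 kb]`; cross-method overlap requires the same
chromosome and intersecting closed intervals.

## Local ancestry

The ancestry model is a hidden Markov chain over the *ordered pair* of
source ancestries of an individual's two haplotypes (K² states; emissions
and dosages depend only on the unordered pair, so this is equivalent to the
K(K+1)/2-state formulation and easier to vectorize). Emissions are binomial
mixtures of the pair's (pseudocount-smoothed) source allele frequencies;
each haplotype independently switches between adjacent SNPs with
probability `1 − exp(−g·r)` toward the individual's stationary proportions
π (from the supervised admixture stage when available, else uniform), with
r in Morgans from a constant 1 cM/Mb map unless a genetic map column is
supplied. Defaults: g = 10 generations, matching roughly half a century of
crossbreeding at a ~5-year generation interval. Posteriors come from scaled
forward–backward, vectorized across individuals; dosages sum to 2 per SNP
to ~1e−9. This single-layer frequency-based HMM replaces two-layer
haplotype-cluster local-ancestry models: it produces the same output
contract (expected ancestry allele dosage per locus) and is testable by
tract recovery (pooled dosage–truth correlation ≥ 0.9 at g = 10, Fst 0.2).

Deviation scanning flags loci whose cohort-mean dosage exceeds the
genome-wide mean by 2 (and 3) SDs; it requires ≥ 100 scanned loci for the
SD to be meaningful. The Grubbs one-outlier test on the maximum uses
`G = (max − x̄)/s` (sample SD), `U = 1 − nG²/(n−1)²` (equal to the
sum-of-squares ratio excluding the maximum), and the t-based one-sided
p-value `min(1, n·P(T_{n−2} > t))` with
`t² = n(n−2)G² / ((n−1)² − nG²)`.

## Synthetic cohorts

Source populations follow the Balding–Nichols model: ancestral frequency
~ U(0.05, 0.95), source frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
divergence F = 0.2 by default (three sources: taurine-like,
African-taurine-like, indicine-like; the Hudson estimator recovers F within
[0.17, 0.23] at 20,000 SNPs). Admixed individuals draw stationary
proportions from Dirichlet(7, 1.9, 1.1) — dominant ancestry averaging ~70%
with wide individual spread — and each haplotype's local ancestry is a
Markov chain with switch probability `1 − exp(−g·r)`, g = 10. Marker maps
are jittered regular grids (~25 kb spacing, matching a typical HD array),
not uniform-random placements: uniform placement occasionally produces
> 200 kb holes that void entire scan windows via the max-gap rule, which a
designed array would not.

Injected sweeps come in two signal classes. *Haplotype sweeps* copy one
fixed donor haplotype into a carrier fraction (default 0.6) of haplotypes
over per-carrier tract reaches drawn Uniform(0, L/2) per side of the core
(default L = 1 Mb): the fraction of carrier pairs still sharing decays
quadratically with distance from the core, the way recombination erodes a
real swept haplotype, so EHH-based statistics peak at the core. A `hard`
variant copies the full rectangular window; its homozygosity signal is flat
across the window and therefore localizes only to window, not core,
resolution. *Ancestry-excess sweeps* (`source_bias`) instead draw each
carrier's tract independently from the biased source's allele frequencies
— selection on standing ancestral variation lifts many different tracts of
one ancestry, not a single clone — and relabel the ancestry truth
accordingly; the `hard` window is the appropriate shape here, since whole
local-ancestry tracts rise in frequency together.

**What the generator does not emulate**: within-source LD (frequencies are
independent across SNPs outside sweep windows), coalescent noise and drift,
recombination hotspots, genotyping error beyond uniform missingness, and
ascertainment bias of array content toward particular ancestries. Passing
power and calibration tests on these cohorts therefore demonstrates the
statistics' mechanics — standardization, truncation, clustering, posterior
decoding — under controlled truth, not performance on real LD structure.

## Problem sizes and experiment design

Null calibration uses 20,000 SNPs × 200 individuals (fraction of
|iHS_std| > 4.5 ≤ 1e−3; XP-EHH moments exact by construction; null
Mahalanobis D̄² within 5% of K at K = 3). Power experiments use 50
replicates of a 2,000-SNP, 50 Mb chromosome with 100 (haplotype sweeps) or
50 (ancestry sweeps) admixed individuals; localization demands the
genome-wide argmax within 250 kb of the core in ≥ 80% of replicates. The
XP-EHH power experiment uses a second admixed cohort (same generator, no
sweep) as the reference population: a reference whose LD structure matches
the object cohort — as a real reference population's does — keeps neutral
log-ratios tight, whereas an LD-free panel of source genotypes swamps the
sweep contrast with background noise.

## Known limitations

- PED/MAP carries no allele orientation; without a sidecar allele table the
  reader orients by major-allele-as-ref (ties alphabetical), which can flip
  rare-allele SNPs relative to the writer's orientation.
- The EM for admixture proportions can be slow to converge for individuals
  near the simplex boundary; such samples are flagged, not refined.
- The ancestry HMM assumes source panels are the true ancestors; with
  mis-specified or internally admixed panels the dosage is a projection
  onto the panel space, not an ancestry estimate.
- iHS/XP-EHH require pre-phased haplotypes; phasing itself is out of scope
  and phased input is taken at face value.
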