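# Methods

## Problem and model

Autozygosity — homozygosity by descent from a recent common ancestor — is
the genomic footprint of inbreeding. In a SNP-array cohort it is proxied by
runs of homozygosity (ROH). This package implements a locus-level
autozygosity pipeline for a single livestock population: detect ROH, compare
genomic inbreeding (F_ROH) with pedigree inbreeding (F_PED), test every
locus's ROH state against inbreeding, birth year and trait PTAs under
permutation-derived genome-wide thresholds, and decompose window haplotype
homozygosity into per-allele additive and recessive effects.

### ROH and the state matrix

A ROH is a maximal run of consecutive homozygous SNP calls within one
chromosome of one individual. The default rule is count-based: ≥ 50
consecutive homozygous SNPs (at ~15 SNPs/Mb this is roughly a 3–4 Mb
span). Heterozygotes always break a run; missing calls break it too unless
`max_missing_in_run > 0`, in which case runs may bridge all-missing gaps up
to the allowance but must start and end on homozygous calls. Mb-based
definitions (3 or 5 Mb) are available through `ROHDefinition(mode="length")`.
Runs are never joined across chromosomes; physical gap size alone never
breaks a run (pure SNP-count logic), which can overstate continuity in
marker-sparse regions — a documented caveat.

From the segment set, the binary state matrix H (individuals × SNPs) has
H[i,j] = 1 when SNP j lies inside any ROH of individual i. Row means of H
are F_ROH (fraction of the genotyped genome inside ROH, SNP-count-based by
deliberate choice; a bp-based variant can be derived from the segment
table). Column means are F_L, the locus autozygosity frequency.

The expected length of an autozygous segment inherited from a common
ancestor g generations back is 100/(2g) cM; on the 1 cM = 1 Mb map used
throughout, 5 Mb at g = 10. This analytic anchor is exposed as
`roh.expected_segment_length_mb`.

### Pedigree inbreeding

F_PED(x) is the kinship of x's parents, computed by the classical recursion
f(a,b) = ½(f(sire(a),b) + f(dam(a),b)) with f(x,x) = ½(1 + F(x)), founders
mutually unrelated, memoized over pairs. Any animal with an unknown parent
gets F = 0 — the convention for cohorts whose founders lack records. If
founders are in truth cryptically related, F_PED underestimates true
autozygosity; the pipeline reproduces (and can demonstrate, via the
simulator) this bias rather than correcting it.

### Association scans and permutation thresholds

At each SNP, ordinary least squares y = β₀ + β₁H + ΣPCᵢ + e, two-sided
t-test on β₁, complete-case analysis. Scans are computed by the
Frisch–Waugh–Lovell closed form (residualize y and all SNP columns against
the covariate block once, then simple regression per SNP) — algebraically
identical to the per-SNP OLS fit, verified against statsmodels in the test
suite, and fast enough to permute. −log₁₀ p is capped at 300 so perfect
fits stay finite. Degenerate SNPs (constant H among complete cases) are
flagged NaN, not errors, and are excluded from permutation maxima.

Genome-wide thresholds: the response alone is permuted across individuals
(covariates stay attached to their individuals, preserving the
covariate–predictor structure under the null); each permutation records the
scan's maximum defined −log₁₀ p; the 95th and 99th percentiles of the
maximum distribution give the suggestive (5%) and significant (1%) levels.
The default 1,000 permutations match standard practice; below 100 a
warning flags unstable percentiles.

Regions: suggestive-exceeding SNPs are clustered per chromosome, clusters
separated by ≤ 1 Mb merged (the merge gap is configurable — published
region tables rarely state the rule, so ours is explicit), regions
spanning < 1 Mb dropped, peak at the maximum −log₁₀ p with ties broken to
the smallest coordinate. Region rows can carry the peak's F_L and a
companion scan's statistic (e.g. the ROH–F_PED peak alongside a trait
region), in both raw and PC-adjusted flavors.

A deliberate scope boundary: trait associations use fixed-effect OLS only.
PTAs are already mixed-model-adjusted genetic merit estimates produced
upstream; no GRM/mixed-model machinery is re-implemented here.

### Principal components

PCA (via scikit-learn) on mean-centered, unscaled columns — ROH states are
binary and unit-variance scaling would inflate rare columns; a scaled
variant sits behind a flag. Missing genotype entries are mean-imputed per
column (H has none by construction). Signs are fixed by making each
component's largest-magnitude loading positive, so score files are
bit-reproducible. Default k = 5 covariates in adjusted models; k is a
parameter.

### Haplotype windows

Phased haplotypes (2 rows per individual; phasing is upstream and out of
scope) are cut into fixed 50-SNP windows per chromosome. Window alleles are
exact-match haplotype strings — no mismatch tolerance, which is correct for
simulated data and a known limitation for error-prone real phasing. Allele
1 is the most frequent (ties: first genomic occurrence). Expected
homozygosity of an allele is its frequency squared, computed per window and
then averaged for genome summaries; observed homozygosity is the fraction
of individuals whose two window haplotypes both equal the allele, so the
per-window total equals the fraction of individuals with two identical
window haplotypes. The most-frequent allele's copy number (0/1/2) feeds
SNP-like additive and recessive OLS models with the same machinery as the
locus scans. Window step defaults to 1 SNP for fine mapping; genome
summaries use step = window (non-overlapping) to keep allele catalogs
tractable — both are exposed.

## The synthetic cohort

Real dairy genotypes of this kind are rarely shareable, so the package
carries a first-class generator whose output exercises every stage with a
known truth.

**Pedigree.** Discrete generations on top of a founder pool (default 80),
each generation sired by few males (default 6 — the AI bottleneck) over
dams drawn from the last three generations; offspring 60 per generation
for 10 generations. With probability 0.3 a mating is "close-line": the dam
is sampled with probability proportional to her kinship with the sire.
These defaults were fixed once so that non-founder F_PED has mean ≈ 0.06–0.09
and a right tail past 0.25 with a handful of more extreme animals — the
regime of a closed, intensively selected population. Parents are strictly
older than offspring, so the pedigree is acyclic by construction.

**Genome and gene drop.** Default desk-scale genome: 10 chromosomes ×
100 Mb × 1,500 SNPs (15 SNPs/Mb, ~68 kb spacing like a 50k bovine array
after QC; a 29-chromosome full-scale config is a parameter change away).
Founder haplotypes are drawn per SNP from a shared spectrum with MAF ~
U[0.05, 0.5] — so chance homozygosity exists and F_ROH exceeds F_PED
slightly even without inbreeding, as in real data. Each transmission draws
a Poisson number of crossovers (Haldane, no interference, 1 cM = 1 Mb) at
uniform positions. Every founder haplotype carries a unique origin label
that propagates through meioses; a locus is truly autozygous iff the two
inherited labels coincide. This exact IBD truth is what ROH calls and
inbreeding estimators are validated against: E[autozygous fraction] equals
F_PED (checked by replicate drops), full-sib offspring average 1/4, and
detected ROH cover all true tracts spanning ≥ 50 SNPs.

**Traits.** PTA-like values: Σ additive effects × dosage + Σ recessive
effects × true autozygosity at the locus + Gaussian noise. Defaults plant
one additive and one recessive locus per trait; the fertility-like trait
(DPR) uses negative effects (recessive −0.4 — inbreeding-depression-like),
the udder-health-like trait (SCS) positive ones. Residual standard
deviations (0.3 / 0.05) are small because PTAs are noise-reduced genetic
estimates, not raw phenotypes. Birth years follow generations.

**What the simulator does not emulate.** No selection on the trait by
default (truncation selection is configured but off), no genotyping error
beyond optional uniform missingness, no LD in founders beyond the shared
frequency spectrum, no crossover interference, no mutation, and phasing is
error-free by construction. Passing tests therefore demonstrate the
correctness and calibration of the machinery under the stated statistical
structure, not robustness to array artefacts or phasing error in real data.
Because inbreeding here is recent (10 generations), simulated ROH are
longer (mean ~19 Mb) than in an old, complex real pedigree.

## Numerical choices

- Genotype missing sentinel is −1, never 0; every downstream operation
  branches on it. Coordinates are 1-based inclusive bp throughout.
- Hardy–Weinberg: exact conditional test on the heterozygote count
  (log-gamma enumeration over the same-parity support), the robust default
  at low MAF; a 1-df chi-square alternative behind a flag. QC filter order
  is fixed and logged: individual missingness → SNP call rate → MAF → HWE,
  each recomputed on the survivors of the previous step, so QC is
  idempotent. HWE is filtered on all retained (related) individuals;
  relatedness inflates HWE departures slightly, a caveat inherited from
  standard practice.
- OLS degenerate cases (constant predictor/response, < 3 complete cases,
  rank-deficiency) return flagged NaNs; t² is evaluated as F(1, df) for
  vectorization.
- PCA beyond the matrix rank warns and flags zero-variance components.
- Kinship recursion recurses on the deeper animal (by pedigree depth), so
  termination at founders is guaranteed; cycles are reported with an
  explicit cycle path at construction.
- All simulator randomness flows through one seeded `numpy` generator;
  rerunning any stage with the same seed is byte-identical.

## Problem sizes used in tests

The default test cohort is reduced (4 chromosomes × 80 Mb × 1,200 SNPs,
6 generations, ~280 animals); calibration checks use 300 individuals ×
2,000 SNPs × 200 permutations; locus-recovery checks use the full
10-chromosome genome with 1,000 offspring. These sizes were chosen as the
smallest at which the statistical assertions (binomial bands, 3-standard-
error checks, ±2 Mb localization) are well-powered.

## Known limitations

- F_PED assumes unrelated founders; with cryptic founder relatedness it
  underestimates autozygosity. The pipeline exposes, but does not correct,
  the discrepancy.
- SNP-count ROH logic ignores physical gaps; in sparse regions a "run" may
  span a large unobserved interval.
- Fixed-effect scans leave any residual stratification beyond the included
  PCs uncorrected.
- Exact-match window alleles make haplotype statistics brittle to phasing
  or genotyping error in real data.
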