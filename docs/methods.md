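# Methods

## Problem and model

`pafcontrast` compares per-SNP population allele frequencies (PAFs) between
a directly genotyped study cohort and reference cohorts available only as
published frequency tables, then asks whether functionally related gene
groups carry unusually many (or few) differing SNPs.

For a SNP with `k` copies of the counted allele among `n` called alleles,
the PAF estimate is `p̂ = k/n` with the 95% Wald interval

    p̂ ± z · sqrt(p̂(1−p̂)/n),   z = 1.96,

clipped to [0, 1]. At exactly monomorphic estimates the normal
approximation collapses (zero-width interval), so a fixed 1% margin is
substituted: `p̂ = 0 → CI (0, 0.01)`, `p̂ = 1 → CI (0.99, 1)`. The margin is
applied only at exactly 0 and 1; there is no continuity correction
elsewhere. `z` is a pinned constant, not recomputed from a normal quantile,
so results are bit-reproducible.

Two cohorts' frequencies are declared **different** when their 95%
intervals are disjoint; touching endpoints count as overlap. This
CI-overlap rule is deliberately conservative relative to a two-sample test:
under equal true frequencies at the default sample sizes (432 vs 224
alleles) its false-positive rate is well under 5% (the acceptance script
measures it; typically under 1%).

### Harmonization and strand ambiguity

Reference tables may count the other allele of the pair and/or encode the
SNP on the opposite strand. Harmonization tries the identity and the
base-complement map; within each, the counted allele may be either member
of the pair (swap), in which case the reference frequency is mirrored
(`f → 1−f`). A/T and C/G SNPs are their own reverse complements, so the
identity and complement resolutions are indistinguishable; these
strand-ambiguous SNPs are removed before any cross-cohort comparison.
Pairs that match under no map are INCOMPARABLE and excluded from all
denominators.

### Quality control

Five filters in a fixed order: sample call rate → strand ambiguity → SNP
call rate → minor allele frequency (computed on called alleles only) →
exact Hardy-Weinberg test. The order is pinned because earlier stages
change later stages' denominators. Defaults: call rates ≥ 0.95, MAF ≥ 0.1,
HWE p ≥ 1e−6. The full-cohort comparison branch applies only the strand
filter (monomorphic and rare SNPs stay in, with boundary intervals); the
stricter thresholds are used on the admixture branch, where rare and badly
called SNPs add noise rather than ancestry signal. The sample call-rate
stage reports low-call samples but keeps them unless `drop_low_call_samples`
is set.

The HWE test is the exact conditional test: given the allele counts, the
heterozygote count has a known discrete distribution under random mating,
and the two-sided p-value sums all configurations no more probable than the
observed one. Weights are computed in exact integer arithmetic
(`math.comb`), which makes the tie comparison unambiguous and lets the
implementation agree with enumeration oracles to machine precision.

### Admixture stratification

Pairwise distance is 1 − mean identity-by-state allele sharing over
mutually called SNPs, `IBS(i,j) = (2 − |gᵢ − gⱼ|)/2` per SNP. Classical
(Torgerson) MDS embeds the matrix: eigendecomposition of the
double-centered squared-distance matrix, coordinates scaled by the square
root of each eigenvalue, eigen-signs fixed by forcing the
largest-magnitude loading positive. The composite ancestry score defaults
to the first axis alone (in two-way admixture the dominant axis carries
the reference-proximity signal); a weighted sum of the top three axes is
configurable, and the direction can be anchored to a reference vector.
The cohort is split at the median score into "closer" and "farther" halves
(larger half "closer" when the count is odd), and the frequency comparison
is re-run independently within each half.

### Group enrichment

Under the null, each grouped comparable SNP is differing independently with
the base rate — the overall differing fraction among grouped SNPs, computed
at full precision by default, or pinned (e.g. to a published rounded
constant such as 0.471) to reproduce externally computed tables. A group
with `k` differing of `n` SNPs gets a binomial tail probability; the
direction is MORE when `k/n` exceeds the base rate, LESS when below, TIE at
exact equality (reported with the smaller one-sided tail). Meta level: the
count of groups with probability < α is tested against Binomial(m, α), and
the MORE/LESS split against a fair coin.

Tail conventions are explicit per test because published tables in this
analysis style are not internally consistent about them. The defaults —
strict upper tail `P(X > k)` for MORE and the meta count, inclusive
`P(X ≤ k)` for LESS and `P(X ≥ k)` for the sign test — are the conventions
under which the bundled published anchor rows reproduce to all four printed
decimals. Three published rows have directions inconsistent with their own
proportions (two below the base rate printed MORE, one above printed LESS,
while their printed probabilities match the opposite tail exactly); the
package reports the self-consistent direction, and the tests document the
discrepancy. Upper tails use the binomial survival function rather than
`1 − CDF`, preserving strict monotonicity deep in the tail. Groups sharing
SNPs are tested independently (no deduplication across groups); groups with
zero comparable SNPs are reported with `n = 0` and excluded from the meta
counts. Known limitation: the binomial null ignores linkage disequilibrium
between SNPs of the same gene, so group probabilities are anti-conservative
in real data; the null-calibration test bounds the effect only for the
independent-SNP generator.

## Synthetic data generator

The generator emulates the study design the pipeline targets, and its
defaults are the study conditions: 34,240 SNPs, 216 diploid study samples
(432 alleles at full call rate), a reference cohort of 224 alleles emitted
as a frequency table (not genotypes, matching how published references are
distributed), 13.1% A/T+C/G loci, 53 functional groups over 705 genes,
2% per-genotype missingness (the study design reports mean call rates
above 98%).

Shared true frequencies are drawn from Beta(0.8, 0.8) — a U-shaped spectrum
typical of candidate-gene array content — plus 5% point masses at 0 and 1
for monomorphic loci; no published spectrum exists for the array, so all
three are configuration, not constants. A fraction `prop_diverged`
(default 0.4) of SNPs gets an additive true-frequency shift in the study
population, magnitude Uniform(0.05, 0.30), direction a fair coin, truncated
to [0, 1] (with the direction flipped when truncation would erase the
shift, so the diverged flag always means a real difference). Enriched
groups multiply the per-SNP divergence probability. Reference records
independently swap the counted allele with probability 1/2 and are
complement-encoded with probability `prop_opposite_strand` (default 0.2),
so harmonization is exercised on every run. Genotypes are Binomial(2, p)
per sample — Hardy-Weinberg proportions, no inbreeding; reference
frequencies are Binomial(n_ref, p)/n_ref draws.

What the generator does **not** emulate: linkage disequilibrium between
loci, relatedness or pedigree structure, genotyping batch effects, and
ascertainment bias of array content. Passing tests therefore demonstrate
correctness of the statistical machinery under independence, not
robustness of the binomial group null to LD in real arrays.

## Numerical choices

- Frequencies are proportions in [0, 1] internally; percent appears only at
  I/O and in reports.
- Bin scheme for the range tables: singleton bins at exactly 0% and 100%,
  interior bins upper-closed ((0,20], (20,40], (40,60], (60,80]), and
  (80,100) open at the top — exact monomorphism is its own category.
- Absolute-difference thresholds (default 10% and 20%) are compared with ≥
  on the percent scale, within the inclusive mid-range window [20%, 80%] of
  study PAF.
- All randomness flows from a single seeded `numpy` generator; the pipeline
  seed overrides the simulation block's seed so one integer pins the run.
- MDS eigenvalues below 1e−12 (relative) are treated as non-positive;
  requesting more axes than the positive spectrum supports truncates with a
  warning.

## Problem sizes in the shipped checks

The test-suite and acceptance-script simulations use scaled problem sizes
chosen to keep the checks fast while leaving the per-SNP sample sizes (432
study alleles vs 224 reference alleles) at the study values, since those
drive the statistics being validated: coverage runs use 10,000 replicates
per frequency, the null false-positive run 20,000 replicates, the
planted-group study 100–200 replicates of 1,500-SNP datasets, and pipeline
smoke runs 500–5,000 SNPs. The generator's own defaults remain at the full
study scale.
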