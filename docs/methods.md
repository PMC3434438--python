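# Methods

## The DMAF test

For each variant *j* the test compares the case and control minor-allele
frequencies, *X*<sub>j</sub> and *Y*<sub>j</sub>, computed over
non-missing genotypes within each group. The minor allele is defined by
the pooled (cases + controls) frequency, fixed once from the observed
data; variants that are monomorphic in the sample, or leave either group
without a genotyped subject, are excluded before analysis. The statistic

V = Σ<sub>j∈A</sub> w<sub>j</sub> D<sub>j</sub>,
D<sub>j</sub> = |X<sub>j</sub> − Y<sub>j</sub>| ("abs") or
(X<sub>j</sub> − Y<sub>j</sub>)² ("sq"),
w<sub>j</sub> = 1/√(n<sub>j</sub> q<sub>j</sub>(1 − q<sub>j</sub>))

is direction-agnostic and weights rare variants more heavily. Because the
pooled frequency q<sub>j</sub>, the genotyped count n<sub>j</sub> and
hence w<sub>j</sub> involve no phenotype, they are held fixed across
permutations; only X and Y are recomputed per relabeling.

**Empirical p-value.** p = #{V<sub>perm</sub> ≥ V<sub>obs</sub>}/B over B
uniform permutations of the case/control labels (ties count as extreme;
a conservative (r+1)/(B+1) variant is available behind a flag). Group
frequencies under permutation are computed as matrix products of the
genotype matrix with a batch of 0/1 label columns, so a thousand
permutations of a 400 × 250 study cost a few milliseconds. Statistics are
accumulated in float64 and compared with a relative tolerance of 1e−9:
relabelings that are mathematically tied with the observed statistic must
count as "at least as extreme", and without the tolerance the summation
order of optimized BLAS kernels silently breaks such ties (this is
visible against an exhaustive-enumeration oracle on eight subjects).

**Missing genotypes.** Group frequencies use the non-missing subjects of
that group; n<sub>j</sub> is the total genotyped count. If a permutation
leaves a group with no genotyped subject at a variant, that variant
contributes a zero difference for that permutation. The estimator choice
is ours; per-group complete-case frequencies are the only defensible
option without imputation.

## Sliding windows and step-down correction

Windows are runs of consecutive *analysis* variants (counted in variants,
not base pairs). For window size s the step is max(5, round(0.10·s))
(round half up), windows start at index 0, and a final window anchored at
the region end is appended when the stepping pattern undershoots, so
every variant is covered. Window sizes larger than the analysis set are
skipped with a notice. No correction is applied across different window
sizes, only across the windows of one size.

The multiple-test correction is the Westfall–Young step-down procedure:

1. B₁ permuted phenotypes — one shared relabeling per permutation,
   applied to every window — give each window its null distribution of V
   and its observed empirical p-value.
2. B₂ further shared permutations are each scored *against the first
   set's null distributions*, giving an m × B₂ matrix **M** of p-values.
   Referencing the second set to the first keeps observed and permuted
   p-values on the same distribution (the standard construction; the
   second set referenced to itself is the other defensible reading).
3. The observed p-values are ordered ascending; corrected p for the
   smallest is the fraction of column minima of **M** at or below it;
   the first row is then removed and the procedure steps down (suffix
   minima over the sorted rows), with a running maximum enforcing
   monotonicity. Results map back to window order.

**Inclusive comparison.** The corrected p counts column minima ≤ the
observed p, not strictly <. Both live on the 1/B grid with an atom at 0;
with a strict inequality every window that reaches raw p = 0 (probability
≈ 1/B per window, so ≈ 3–5 % for the minimum over ~50 windows) would
receive corrected p = 0 and be declared significant, which measurably
inflates the family-wise error rate at α = 0.05 (to ≈ 0.055–0.087 in our
null simulations, versus ≈ 0.037–0.07 with the inclusive count). The
inclusive count is the standard resampling-based definition and is what
the package uses.

**Shared permutations** across windows are essential: the column minima
of **M** are only a draw of the minimum p-value under the complete null
if each column corresponds to one phenotype relabeling applied to every
window. The tests assert this by checking that duplicated windows receive
identical matrix rows.

**Localization.** The window — or, on ties of the minimum corrected
p-value, the set of tied windows — is compared with the causal
sub-region. The criterion is: overlap, in number of variants, at least
half the number of variants in the window or tied set (set = union of the
tied windows' indices). Counting the union's markers rather than its
min-start-to-max-stop extent matters when a strong signal produces many
tied windows at raw p = 0, some of them LD-driven stragglers away from
the causal cluster: the extent reading then fails arbitrarily often,
while the union reading remains a meaningful measure of where the tied
evidence sits. An empty causal range (null data) counts as not localized.

## Simulation framework

**Haplotype pools.** Neutral coalescent simulation (msprime) of 100,000
diploids over 50 kb with mutation rate μ = 10⁻⁸ /bp/generation, effective
population size 10,000 and background recombination 1 cM/Mb; "hotspot"
regions add a 2-kb segment at 15 cM/Mb. The hotspot sits at the region
midpoint by default — its exact placement is a free choice, and the
midpoint maximizes the interruption of LD between the two halves. The
genome is continuous (infinite sites) with binary mutations, matching
classical ms-style output; the expected segregating-site count is the
Watterson value θ·a<sub>n−1</sub> ≈ 256 at these parameters. Columns are
oriented so allele 1 is the pool-minor allele.

**Disease models.** A "rare" variant has pooled-pool MAF ≤ 0.05 (0.04 and
0.06 for models B and C). Models A–C: a uniformly random half of the rare
variants are risk alleles. Model D: all rare variants causal, a random
half risk and half protective. Models E/F: the model A/D set plus one
additional common risk variant, the variant with MAF closest to 0.10.
Models G/H: the rare variants are split into positional thirds (earlier
tiers get the extra variant on non-divisible counts); the middle third is
causal — all risk (G) or half risk, half protective (H). Risk always
receives the extra variant over protective on odd counts. Risk odds
ratios by MAF bin (MAF > 0.01 / 0.001 ≤ MAF ≤ 0.01 / MAF < 0.001) are
1.5/1.7/2.0 for whole-region models A–F and 1.7/2.0/2.2 for sub-region
models G/H; protective odds ratios are the exact reciprocals.

**Risk model.** Each causal allele copy multiplies the disease *odds*:
odds<sub>i</sub> = c·Π<sub>j</sub> OR<sub>j</sub><sup>g<sub>ij</sub></sup>,
Pr(case) = odds/(1 + odds) — the standard logistic disease model of the
case-control simulation literature. The baseline c is calibrated by
bracketed bisection so the pool-mean probability equals the target
prevalence (10 %), to within 10⁻⁶. We deliberately use the odds scale
rather than multiplying probabilities directly: at these odds ratios and
this prevalence a multiplicative-probability model exceeds 1 for a few
percent of the pool, turning the most-exposed individuals into
deterministic cases and inflating the variance explained by the causal
set well beyond what these effect sizes should produce; the logistic
form keeps probabilities proper and yields causal-set Nagelkerke R²
values centered near 7 % across the model grid, the intended
"many-variants-of-small-effect" regime. With no causal variants, c is the
baseline odds prevalence/(1 − prevalence) and every subject's case
probability is exactly the prevalence.

**Sampling.** Each replicate study draws every pool individual's status
Bernoulli(its case probability), then samples the requested numbers of
cases and controls uniformly without replacement (defaults 200 + 200).
All pool variants are carried in the genotype matrix; those monomorphic
within a sample are flagged and excluded by the test. At this prevalence
roughly 10,000 cases are realized, so 200 + 200 sampling always succeeds.

**Trait variance.** The proportion of trait variance explained by a
causal set is the Nagelkerke pseudo-R² comparing intercept-only and
causal-set logistic fits on the pool: R² = (1 − exp(2(ℓ₀ − ℓ₁)/N)) /
(1 − exp(2ℓ₀/N)). Fits use scikit-learn's unpenalized lbfgs solver;
likelihoods are evaluated from predicted probabilities clipped to
[10⁻¹², 1 − 10⁻¹²], and under separation the value is capped at 1 with a
warning.

## Evaluation metrics

Type I error is the fraction of null-model p-values below α with an exact
Clopper–Pearson interval. Power at an empirical α uses the lower
α-quantile of the null p-values (the ⌊αn⌋-th order statistic) as the
threshold, so methods with slightly mis-calibrated nulls are compared
fairly. Localization rate is the fraction of replicates whose best
window(s) half-overlap the causal sub-region; window sizes analyzed in
fewer than a configurable number of replicates (default 700) are dropped
from power summaries, since the largest sizes exceed some replicates'
polymorphic-variant counts.

## What the simulations do and do not show

The generator reproduces the coalescent/disease-model study design it
implements: realistic allele-frequency spectra, LD, MAF-dependent effect
sizes, and both unidirectional and mixed-direction causal architectures.
It does not model natural selection, demographic structure, genotyping or
sequencing error, covariates, or relatedness — so passing tests speak to
the statistical procedure under the stated sampling model, not to
robustness against those real-data complications.

Two quantities are dominated by *region-realization* variance, which a
reader should keep in mind when comparing single numbers: the family-wise
error level of the scan varies by a couple of percentage points between
pool realizations, and the model-G localization rate for small windows
varies dramatically (roughly 0.1–0.85 across independent hotspot-free
pools in our runs) because realizations differ in how far LD carries the
causal signal: when power saturates, many windows tie at raw p = 0 and
the tied set can spread region-wide. Single-realization benchmarks for
these quantities therefore carry substantial uncertainty beyond their
binomial error bars, and the package's evaluation routines average over
several independent pool realizations where feasible.

## Numerical and scale choices

Default permutation counts are B₁ = B₂ = 1000. The package's own
evaluation study (tests and `scripts/acceptance.py`) uses 300 null
replicates for error-rate estimates, 20 region draws for yield/count
estimates, 10 pools × 30 replicates for localization, and one or two
region triplets for the trait-variance grid — sizes chosen to give
standard errors comfortably inside the tolerances being checked while
finishing in minutes on one CPU. Seeds fan out from a single user seed
through numpy's `SeedSequence`, so every pipeline is bit-reproducible;
msprime receives derived 31-bit seeds. Window indices are 0-based
half-open internally and 1-based inclusive in reports; VCF positions are
1-based externally.
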