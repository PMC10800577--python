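# Methods

`epinet` turns a case-control genotype cohort into a direction-signed
gene–gene interaction (GI) network. This note records the models, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the limitations a user should keep in mind.

## The two-stage SNP-pair scan

The unit of testing is an unordered pair of SNPs assigned to disjoint gene
sets ("intergenic" pairs, so every interaction links two different genes).

**Stage 1 — log-linear screen.** For each pair the 3 × 3 × 2 table of
genotype A × genotype B × phenotype is compared against the Kirkwood
superposition approximation (KSA) of the homogeneous-association log-linear
model:

    p̂(i,j,k) ∝ p(i,j) · p(i,k) · p(j,k) / ( p(i) · p(j) · p(k) ),

normalised over the 18 cells, with cells losing any required marginal set to
zero. The screening statistic is

    τ = 2 · ( LL_saturated − LL_KSA ),   p_screen = P( χ²₄ ≥ τ ),

with 0·log 0 ≡ 0 and 4 = (3−1)(3−1) interaction degrees of freedom. Because
the KSA log-likelihood never exceeds the maximised homogeneous-association
log-likelihood, τ upper-bounds the exact 4-df interaction likelihood ratio —
the screen can only over-select, never under-select, relative to the exact
test (verified against an iterative-proportional-fitting oracle in the test
suite). A pair whose observed count falls in a zero-KSA cell has no defined
τ and is carried as `degenerate`.

Counting is plain vectorised arithmetic: genotype-by-phenotype indicator
matrices are built once and each cell of a block of pairs is an inner product
of two indicator columns. Missing genotypes and phenotypes drop out of every
cell automatically (complete-case analysis per pair; no dosage imputation).

**Stage 2 — logistic interaction odds ratio.** Pairs with
`p_screen ≤ screen_alpha` get a maximum-likelihood fit of

    logit P(case) = β₀ + β₁·gA + β₂·gB + β₃·gA·gB,

on complete cases with minor-allele dosage coding 0/1/2, by iteratively
reweighted least squares (relative log-likelihood tolerance 1e-8, at most 50
iterations). The reported quantities are the Wald p-value of β₃ and the
interaction odds ratio OR = exp(β₃). Rank-deficient designs (e.g. a
monomorphic SNP) are `degenerate`; IRLS failure or |β₃| > 15 (a
quasi-separation proxy) is `non_converged`, and no OR is reported — there is
no Firth correction, matching the flag-and-drop behaviour of the standard
tools. The Wald (not likelihood-ratio) test is used because the OR and its
standard error are the quantities the workflow propagates.

`screen_alpha` defaults to 1e-4: the screen is deliberately looser than the
1e-5 nominal cutoff applied to the collapsed gene-pair calls, so the second
stage sees every pair that could matter downstream.

**Allele-coding caveat.** β₃ is defined with respect to minor-allele coding.
Flipping the coding of one SNP of a pair negates β₃ (OR ↦ 1/OR). A variant
whose population frequency sits near 0.5 can legitimately change orientation
between a generating model and an ascertained sample; interaction directions
for such variants are coding conventions, not biology.

## Gene-level collapsing

A SNP represents a gene when its position falls in the gene body or promoter
(BED intervals, 0-based half-open; a 1-based variant position p is inside
[s, e) iff s ≤ p−1 < e). Multi-assignment is allowed and a pair is eligible
only if the two SNPs' gene sets are disjoint — the strictest reading of
"between different genes". Per gene pair, the contributing SNP pair with the
minimum Wald p supplies the gene-level p and OR (ties broken by
lexicographically smallest SNP-id pair). The collapsed p is deliberately not
adjusted for the number of SNP pairs inside the gene pair; the min-p
convention is the method's definition, and the multiplicity is instead
absorbed into the genome-wide test count below.

## Multiple testing and the network

The assumed test universe is m = 200,000,000 gene pairs (≈ C(20000, 2) for
the protein-coding genome) rather than the number of pairs actually
measured; untested pairs count as non-discoveries. Bonferroni control gives
0.05 / 2×10⁸ = 2.5×10⁻¹⁰. Benjamini–Hochberg step-up control takes the
largest rank k with p(k) ≤ k·α/m; with 9.5 million discoveries among 2×10⁸
assumed tests at α = 0.05 the cutoff is 2.375×10⁻³. Both m and the nominal
cutoff (default 1e-5) are configuration parameters.

Direction: OR > 1 is "increased risk", OR ≤ 1 "decreased or no risk" — the
no-effect point belongs to the latter bucket by its name. Hub analysis keeps
two-fold GIs only (OR > 2 or OR < 0.5, strict inequalities, as the
thresholds are stated), restricted to interactions whose representative SNPs
are gene-body-assigned ("intragenic" SNPs; promoter-only GIs stay in the
global table but are excluded from hub counting), and tallies per-gene
degrees separately by direction, sorted by total degree.

## Quality control

Filters run in a fixed order and every removal is reconciled in the QC
report: (1) variant call rate (remove iff call rate < 1 − geno), (2) MAF,
(3) exact Hardy–Weinberg tiers, (4) sample call rate, (5) relatedness.
Presets: `array` (geno 0.02, MAF 0.01, HWE 1e-3, mind 0.1) and `imputed`
(geno 0.05; HWE failing below 1e-5 in *both* cases and controls, or below
1e-6 in controls alone, or below 1e-10 in cases alone — the tiered wording
is read literally). QC is idempotent on the cohorts it is designed for, and
this is tested.

The exact HWE test conditions on the allele counts and sums the
probabilities of all heterozygote counts no more probable than the observed
one (the plain exact test; no mid-p variant, matching the dominant
convention). The conditional distribution is computed in log space through
the ratio recurrence P(h+2)/P(h) = 4·n_hom_minor·n_hom_major /
((h+1)(h+2)); an independent log-factorial enumeration serves as the test
oracle across every configuration with ≤ 500 individuals.

Relatedness uses the method-of-moments PI-HAT = P(IBD=1)/2 + P(IBD=2)
estimated from IBS sharing given sample allele frequencies, computed for all
pairs at once with one-hot matrix products, on a greedily LD-pruned panel
(windowed dosage-correlation, r² cap). Negative intermediate IBD
probabilities are clamped at zero before combining and the final estimate is
clamped to [0, 1]. Pairs with fewer than `min_overlap` (default 200)
jointly-called variants are flagged unreliable and never acted on. Exclusion
at PI-HAT ≥ 0.1875 (second degree) removes, repeatedly, the sample with the
most flagged partners (ties broken by removing the lexicographically later
id, so originals win over appended duplicates).

*Scaled-down limitation:* full-scale workflows estimate PI-HAT on tens of
thousands of LD-independent SNPs, where the estimator's sampling noise is
negligible. At desk scale (~1,300-SNP panels) the noise standard deviation
is ≈ 0.03, so a small fraction (~10⁻⁴) of truly unrelated pairs crosses the
0.1875 threshold and a few percent of samples may be removed spuriously.
Recall of genuinely related pairs (duplicates in the tests) is unaffected.

## The synthetic-data generator

The generator emulates a post-QC imputed case-control dataset: biallelic
SNPs with per-variant MAF drawn uniformly from `maf_range`, genotypes
binomial(2, MAF) under Hardy–Weinberg equilibrium, genes laid on one
synthetic chromosome (gene g's body at offset g·10⁵ + 10⁴ with one SNP per
100 bp; promoter 2 kb upstream), and a logistic disease model

    logit P(case) = β₀ + Σ_planted ( β₁·gA + β₂·gB + β₃·gA·gB ),

with β₀ = logit(baseline prevalence, default 0.01). Sampling is
retrospective: population individuals are drawn (batched, capped at 10⁷
draws with an explicit quota failure) until the case and control quotas
fill. Under outcome-dependent sampling only the intercept of a logistic
model is biased, so the interaction OR — the quantity the pipeline reports —
remains recoverable; this is why the disease model matches the follow-up
test's model exactly. The last gene's promoter is extended over its
neighbour's final body SNP so multi-assignment is always exercised.

`inject_artifacts` adds what QC must remove: uniform missingness,
heterozygote-deficient variants (only homozygotes at allele frequency 1/2 —
maximal HWE violation that still passes the MAF filter), and appended
duplicate samples, all recorded in a manifest for recall scoring.

Not emulated: linkage disequilibrium structure, imputation uncertainty,
population stratification, sex chromosomes, and genotyping error beyond
missingness. Passing tests therefore demonstrate the statistical machinery
is calibrated and recovers planted effects under clean assumptions; they do
not demonstrate robustness to confounding or LD, which the method inherits
from standard GWAS practice.

## Standing studies and their problem sizes

Chosen once as desk-scale equivalents of the workflow's conditions:

* **Null calibration** — 500 cases + 500 controls, 150 single-SNP genes →
  C(150,2) = 11,175 intergenic null pairs, screen threshold 1 so every pair
  reaches the follow-up. Expected: type-I error ≈ 0.05 at α = 0.05 and
  uniform Wald p-values (Kolmogorov–Smirnov).
* **Effect recovery** — 200 replicates of 1,000 cases + 1,000 controls with
  one planted pair at interaction OR = 2 (mains 0.15): 95% Wald intervals
  should cover ln 2 ≈ 95% of the time and the mean estimate should sit
  within 0.05 of ln 2.
* **Ranking** — 100 replicates of the same effect inside a 48-gene scan
  (1,128 gene pairs) at the default screen: the causal SNP pair should be
  the top Wald hit in ≥ 95% of replicates.
* **QC recall** — 150 + 150 samples, 1,350 variants, 10 injected HWE
  violations, 4 duplicates, 1% missingness: 100% recall of both artifact
  classes with planted causal SNPs retained.

All randomness flows from explicit `numpy.random.Generator` seeds (child
seeds derived by `SeedSequence`); identical configuration and seed give
byte-identical outputs end to end.

## Known limitations

* No covariate adjustment (ancestry principal components, sex) in the
  interaction model; apply the method to stratification-checked cohorts.
* Min-p collapsing favours gene pairs with many SNP pairs; the flat
  genome-wide m compensates globally but per-pair p-values are not
  within-pair multiplicity-adjusted (by design, see above).
* The screen's χ²₄ reference combined with the upper-bounding τ makes stage
  1 slightly anticonservative, which is intended for a screen; final
  inference rests on the stage-2 Wald p.
* Interaction ORs depend on allele coding (see the caveat above); compare
  directions across datasets only under a shared coding convention.
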