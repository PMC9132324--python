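# Methods

This note documents the models implemented in `isoratio`, the numerical
choices behind them, what the synthetic cohort generator does and does
not emulate, and the known limitations.

## Differential isoform ratio (DIR) testing

**Ratio vectors.**  A gene's per-sample isoform abundances (TPM scale)
are normalized to sum to 1; samples whose abundances are all zero for the
gene carry no ratio information and are dropped (and reported).  Genes
with fewer than two isoforms, or fewer than two retained samples in
either group, are reported as untestable with a reason code rather than
raising — cohort-level runs should not die on degenerate genes.

**LDA separation statistic.**  The ratio space is rank-deficient (rows
sum to 1), so the coordinate with the smallest overall variance is
dropped and the pooled within-group scatter is pseudo-inverted; the
Fisher discriminant direction is w = S_w⁺(μ₁ − μ₂), and the statistic is
(μ_PT − μ_Met)²/(σ²_PT + σ²_Met) on the projections, with unbiased (n−1)
variances.  The statistic is invariant to affine rescaling of the
projection axis, so the arbitrary normalization of w is irrelevant.
Degenerate cases: both group variances zero with equal means → 0; with
unequal means → +∞ sentinel.

**Permutation test.**  The discriminant direction is *refit* for every
relabeling — refitting is the conservative reading when only "the
statistic was recalculated" is specified, and it keeps the null
distribution honest when the direction itself is data-driven.  When the
number of distinct labelings C(N, n₁) is at most `n_iter`, all labelings
are enumerated and p is exact (fraction of labelings, observed included,
reaching the observed statistic); otherwise p = (b+1)/(n_iter+1) from
`n_iter` sampled relabelings, which is valid and respects the resolution
floor 1/(n_iter+1).  Permuted statistics are compared to the observed one
with a 1e-9 relative tolerance so that mathematically equivalent
labelings (e.g. the complement labeling) are not lost to float noise.
Internally the permutations are evaluated in vectorized batches using the
identity S_w = S_t − (n₁n₂/N)δδᵀ (the total scatter S_t is
labeling-invariant), which makes 5×10⁴ refits per gene cheap.
Default `n_iter` = 10,000 (resolution 10⁻⁴); the calibration and oracle
checks in the test suite use 999 and 50,000 respectively.

**PCA-combined model.**  PCA is computed on mean-centered, unscaled
proportions (pooled centering across both groups).  Components with
variance ≤ 1e-12 × the leading variance are treated as zero-variance and
removed; an absolute floor of 1e-24 on the leading variance catches the
identical-samples case, where centering noise at machine epsilon would
otherwise masquerade as signal.  For n isoforms at most n−1 components
survive.  Per component, three two-sample tests are available:

* Welch's t (Welch–Satterthwaite df; two zero-variance groups give p = 1
  on equal means, machine-epsilon on unequal);
* a permutation-moment independence Z test: T = Σ of group-1 values
  standardized by its exact conditional moments under label permutation,
  E[T] = n₁·v̄ and Var[T] = n₁n₂/(N−1)·Σ(v−v̄)²/N, referred to the
  standard normal — the asymptotic two-sample case of
  conditional-inference frameworks;
* the Wilcoxon rank-sum test (exact enumeration when N ≤ 12 without
  ties, otherwise normal approximation with tie and continuity
  corrections).

**Combination.**  Fisher's method uses X = −2Σln p against χ² with 2m
df; p-values are clamped at machine epsilon before the log.  The
harmonic-mean p uses the asymptotically exact Landau tail: 1/hmp is
referred to the Landau distribution with location ln m + 0.874367 and
scale π/2.  `scipy.stats.landau` is parameterized as the S0 extremal
stable (α = 1, β = 1) — verified in the test suite both against the
textbook integral density (which equals scipy's at loc = ln(π/2),
scale = π/2) and against a Monte-Carlo null of the harmonic mean — so the
constants apply to it directly.  A single p-value passes through both
combiners unchanged.

**The geometric-mean statistic.**  p_new = √(p_t·p_coin) of the two
Fisher-combined families is the recommended fast surrogate for the
permutation p.  It is *not* a calibrated p-value under the null — it is
bounded by its two factors but can undercut each one's level — and it is
used as a ranking/screening statistic with BH adjustment applied on top,
exactly as intended.  The test suite asserts its definitional identity
(p_new² = p_t·p_coin) and its between-factors bound, not null
calibration.

**Benjamini–Hochberg.**  Implemented directly (≈10 lines of step-up)
so that missing p-values pass through as missing; verified against
statsmodels on complete vectors.

**Test comparison.**  Candidates are scored against the permutation
reference by Pearson r of p-values, Spearman ρ, Pearson r of log
p-values, and Youden's J = sensitivity + specificity − 1 at α ∈ {0.05,
0.01, 0.001}, treating reference calls at α as ground truth.  J is
undefined (NaN) when the reference has no positives or no negatives at
that α — which happens by construction when α is below the permutation
resolution floor.

## Sample quality control

Removal is on the strict inequality, taken literally: a sample is kept
iff purity ≥ 0.70 **and** 3'-bias score ≤ 0.55, so boundary samples
survive.  Samples missing a score for an active filter are excluded with
reason "missing" — conservative, and configurable by disabling the
filter.  Both scores are consumed as metadata columns; computing them
from reads is out of scope.  The sensitivity analysis removes samples
one at a time in a chosen order (most-biased-first, least-pure-first,
etc., optionally restricted to one sample type) and re-runs any per-gene
test, truncating when a group would fall below two samples.

## Per-sample clustering

The two-group quasi-Poisson GLM (log link, metastatic indicator) is
saturated, so the fit is closed-form: fitted means are the group means,
the coefficient is their log ratio, dispersion φ = Pearson X²/(N−2) with
φ = 1 exactly when X² = 0, and the Wald t = β/SE with
SE = √(φ(1/(n_PT·μ̂_PT) + 1/μ̂_Met)) is referred to t with N−2 df
(two-sided, direction taken from the coefficient sign).  Quasi-likelihood
does not require integer responses, so TPM values are used as-is.  Zero
group means are floored at 0.5 (half-count continuity) before the log
ratio and SE, keeping boundary fits finite with the correct sign; an
all-zero contrast returns sign 0, p = 1.  The closed form is vectorized
across all isoforms × metastatic samples (the primary-pool mean and the
dispersion are shared across a row because the metastatic residual is
zero at saturation) and cross-checked against statsmodels GLM in tests.

Digitization is direction-specific: +1 iff sign > 0 and p < 0.05, −1 iff
sign < 0 and p < 0.20.  The liberal down threshold reflects Poisson-like
data with low medians, where a single sample's decrease rarely reaches
conventional significance.  Isoforms altered in strictly more than 13%
of samples are kept.  K-means (plain Euclidean on the ternary entries,
10 restarts, seeded) is run over a k range; k is chosen as the argmax of
the second difference of the WSS curve — an explicit, reproducible
stand-in for reading the elbow by eye — with a manual override parameter
for exploratory use.  Cluster × metadata enrichment uses the one-sided
Fisher exact test; 0.5 continuity is added to the odds ratio only when a
cell is zero (the p-value stays exact).  Infiltrate classification is
2-means on the sample profiles restricted to the immune isoform rows,
labeling the cluster with the higher +1 rate.

## Junction validation

Junction coordinates follow the STAR `SJ.out.tab` convention (1-based,
intron-inclusive), stored as a long TSV with a unique-read count column.
For a skipped exon, inclusion support is the average of the two flank
junction counts and the tested fraction is skip/(skip + inclusion); for
alternative promoters and other two-junction events the fraction is
a/(a+b) — alt-terminal and mutually-exclusive events are structurally
identical and reuse it.  Samples with zero reads over the event are
excluded, not imputed.  The group test is the one-sided rank-sum with
direction fixed in advance by the abundance-based expectation; fractions
are scale-invariant in the read depth.

## Enrichment

Foregrounds are percentile cuts of the ranked list (genes with a p-value
only): size = ⌈fraction × n⌉ — ceiling is forced by the worked counts
27/538 and 24/468 at 5%, which nearest-rounding would break.  The
background is the *remaining* genes (universe minus foreground).  The
one-sided hypergeometric p is deliberately unadjusted: annotation sets
are strongly dependent and share a constrained universe, which breaks the
BH independence heuristics; the empirical FDR (mean number of
annotations passing α on uniformly random foregrounds of the same size)
is the replicated alternative control.

## The synthetic cohort generator

The generator's job is statistical structure, not biological realism at
the sequence level.  Per gene: isoform count uniform on a configured
range; baseline proportions from a symmetric Dirichlet(2); gene base
abundance LogNormal(meanlog 3, sdlog 1) in TPM (median ≈ 20).  Planted
isoform switches move `dir_delta` proportion mass between the two
largest-baseline isoforms in the metastatic group (borrowing
proportionally from the others if the source isoform is too small to
give up the full delta); per-sample proportions are then drawn from a
Dirichlet centered on the group vector with the configured concentration
(default 25, putting single-sample proportion noise near ±0.1).  Gene
totals get per-sample lognormal noise (sdlog 0.3), per-gene×batch
factors (log-sd `batch_sd`), and 2^lfc effects on planted DE genes.

Distortions: purity per sample is Beta-distributed per group (a zero
second parameter is the point mass at 1); every sample is mixed with a
fixed contaminant profile — the cohort baseline for ordinary samples, an
immune program (5% of genes upregulated 8×) for designated infiltrate
samples, reproducing the correlated up-regulation block that immune
infiltrate creates.  3'-fragment bias moves a fraction
f = strength · max(0, (bias − 0.4)/0.6) of non-fragment mass onto a
designated fragment isoform, conserving the gene total exactly; the
piecewise-linear form is an artifact choice placing the QC cutoff (0.55)
inside the active range — only the existence and direction of the skew
matter downstream.  Finally a detection floor (0.25 TPM) zeroes very low
abundances, emulating quantification dropout; this is what gives rank
tests the tie problems seen on real data.  Junction counts are Poisson
around depth·ψ / depth·(1−ψ) with ψ the true (pre-distortion) inclusion
proportion of the event's tracked isoform.

One global seed drives separate spawned streams per stage (structure,
proportions, totals, QC scores, junctions), so identical config + seed
reproduce the cohort bit for bit.  DIR, DE and immune gene sets are drawn
disjoint so planted effects can be scored unambiguously.

What it does **not** emulate: read-level artifacts (mapping, GC bias),
transcript sequences, realistic isoform-count distributions per gene,
correlated gene-gene co-expression beyond the immune block, or
negative-binomial count noise (inputs are TPM-scale and continuous).
Passing tests therefore demonstrate correctness of the statistical
machinery under controlled violations — impurity, 3' bias, dropout,
batches — not performance on any particular real dataset.

A separate scenario generator (`generate_subgroup_cohort`) plants two
metastatic subgroups with disjoint isoform up-regulation programs over a
shared primary pool, for end-to-end checks of the clustering pipeline
and infiltrate classification.

## Problem sizes and tolerances in the shipped checks

The acceptance suite uses: 50 genes at 5+5 samples with n_iter = 50,000
for the sampled-vs-exhaustive permutation check (3-standard-error
agreement); a 500-gene null cohort (40 vs 60, no planted effects,
purity 1, bias 0) with n_iter = 999 for calibration (KS at the 1% level;
the 10⁻³ resolution of the permutation p is negligible against the KS
critical value at n = 500); 200-gene cohorts at 50 vs 150 for the power
curve over delta ∈ {0.1, 0.2, 0.3}; all 2×2 tables with N ≤ 30 for the
exact-enumeration enrichment oracle; and 100 replicates for the junction
round trip (ψ 0.8 → 0.4, depth 200, 30 vs 30).  These sizes were chosen
so the whole suite runs in a few minutes while keeping every check
statistically meaningful.

## Known limitations

* The geometric-mean statistic is uncalibrated by design (see above);
  treat `p_geo` as a screening statistic, not a literal tail
  probability.
* Fisher's method assumes independent per-component p-values; PCA
  coordinates are uncorrelated but not independent, so cohort-level
  calibration is approximate (and verified empirically on null
  cohorts).
* The independence Z test is asymptotic; at very small group sizes the
  permutation model is the appropriate reference.
* The quasi-Poisson caller assumes the primary pool is homogeneous per
  isoform; strong primary-side substructure will inflate dispersions and
  mute calls.
* The elbow rule (max second difference of WSS) is one formalization of
  a visual heuristic; `k_override` exists because no automatic rule is
  authoritative.
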