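# Methods

## The correlation model

The question the pipeline answers is observational: does a gene's bulk
tumor expression co-vary with cytotoxic T-cell infiltration? Infiltration
is not measured directly; it is proxied per sample either by *CD8A*
expression (the CD8 α-chain, expressed by the infiltrating cells
themselves) or by the cytolytic activity score
CYT = √((GZMB + c)(PRF1 + c)), the geometric mean of granzyme B and
perforin with pseudocount c = 0.01 TPM. The pseudocount keeps samples with
zero expression of one effector finite and near zero instead of exactly
zero; CYT is symmetric in its two genes, scales linearly under joint
rescaling, and lies between the two expression values when c = 0.

Within each cohort, every gene is correlated with the proxy by the sample
Pearson coefficient; the p-value is the two-sided t-test
t = r√((n−2)/(1−r²)) on n−2 degrees of freedom, which is exact under
bivariate normality and a standard large-sample approximation otherwise.
Cohorts are analysed independently — cancer types differ in baseline
immune infiltration and expression, so pooling samples would induce
Simpson-type artefacts; aggregation happens only at the level of
coefficients, via the per-gene median across cohorts. Medians of an even
number of cohorts use the mean of the two central values. Genes are ranked
by median r (descending; ties broken lexicographically by gene id so
output is byte-stable) and assigned percentile 100·(rank−1)/(G−1) within
the G ranked genes. The percentile is relative to whatever gene universe
the input matrix provides; universe selection is the caller's decision.

Defaults that matter:

- **Correlation scale**: log₂(TPM+1) (default) or raw TPM. TPM is heavily
  right-skewed; the log scale makes the Pearson coefficient far less
  sensitive to a few extreme samples and is the documented default. A
  `--scale tpm` mode is retained.
- **min_samples = 10** per cohort: below this the t-approximation and the
  coefficient itself are too unstable to report; skipped cohorts are
  flagged `low_n`, and genes constant within a cohort are flagged
  `zero_variance` for that cohort only.
- **Significance counting**: a cohort counts as positive-significant at
  unadjusted two-sided p < 0.05 with r > 0; alpha is a flag. No
  multiple-testing correction is applied to this per-gene count across
  cohorts (29 weakly dependent tests summarised as a count, not a
  discovery list); BH adjustment is available as a utility
  (statsmodels' step-up) wherever a vector of p-values is reported.

## Stratified differential expression and enrichment

Samples of one cohort are ordered by the stratifying gene's expression
(stable sort on (value, sample id), so ties resolve deterministically);
the bottom and top ⌊n/3⌋ samples form the low and high terciles. Per gene,
the effect size is log₂((median_high + 1)/(median_low + 1)) on the TPM
scale — a median ratio with pseudocount 1 TPM, robust and always finite —
and the test is the Mann–Whitney U. The U p-value is computed by exact
enumeration of group assignments whenever the enumeration is no larger
than C(16,8) (this covers both groups ≤ 8 as well as very unbalanced
small comparisons, and handles ties correctly), and otherwise by the
tie-corrected normal approximation without continuity correction, which
is calibrated to a 5% ± 1 rejection rate under the null in the test
suite. An all-tied comparison returns p = 1. This distribution-free
scheme is deliberately self-contained and oracle-testable; it is not a
count-model DE engine (no dispersion shrinkage, no GLMs), so its
fold-changes and adjusted p-values approximate rather than reproduce
what a full RNA-seq DE pipeline would report.

Gene-set signal is assessed two ways: over-representation of the selected
(up-regulated) genes in each set by the upper-tail hypergeometric
p = P(X ≥ k | N, K, n) with BH across sets, and a rank-enrichment p
comparing in-set vs out-of-set fold-changes by Mann–Whitney (two-sided by
default; one-sided available). Selection for over-representation defaults
to unadjusted p < 0.05 with positive fold-change: with genome-sized
universes and modest single-cohort effects a BH cut can empty the
selection entirely, while the hypergeometric test already conditions on
the selection size; the DE p-values' null calibration supports the
unadjusted cut.

The induction-attenuation contrast takes two precomputed DE profiles
(e.g. stimulated-vs-unstimulated in control cells and in knockout cells),
aligns them on a gene subset, and summarises Δ = lfc₁ − lfc₂ by its median
and a two-sided exact sign test (zeros dropped). Paired designs are not
modelled.

## Screen enrichment

Counts are normalised to counts-per-million per condition (the
normalization is scale-invariant and matches the "normalized counts"
convention of pooled screens); each guide's enrichment is
log₁₀((cpm_sel + 0.5)/(cpm_ctl + 0.5)); a gene's score is the mean of its
guides (median available via `--agg median`; mean is more stable at 3–4
guides per gene), ranked descending with lexicographic tie-break. An
optional second control arm (e.g. irrelevant T cells) is reported side by
side. No p-value machinery (robust rank aggregation, permutation nulls)
is attached: the re-analysis use-case is hit ranking, and the simulation
tests verify that a fixed gene's rank percentile is uniform across seeds
in the absence of selection.

## The synthetic generators

**Expression.** Within a cohort, sample i draws an infiltration factor
z_i ~ N(0,1); gene g draws log₂(TPM+1) = μ_g + β_g z_i + σ_g ε (ε standard
normal), clipped at zero, and TPM = 2^x − 1. On the log scale the
population correlation of genes g and t is
(β_g β_t)/√((β_g²+σ_g²)(β_t²+σ_t²)), which serves as the closed-form
oracle for parameter-recovery tests. Means are set high enough (μ ≥ 5,
markers 7) that zero-clipping is rare (<1%) and does not visibly bias
correlations.

The TCGA-like preset fixes the study conditions of the pan-cancer
analysis: 29 cohorts with realistic sizes summing to 9,045 samples;
markers CD8A/GZMB/PRF1 with β = 2, σ = 0.5; named immune effectors (IFNG,
B2M, GZMA, CD274) and a 50-gene immune-linked block with loadings spread
over [0.35, 1.2]; MBNL1 with cohort-specific loadings chosen to plant
r = 0.27 in the melanoma cohort (n = 410, so the planted correlation's
expected p ≈ 2·10⁻⁸) and positive, well-powered correlations in 27 of 29
cohorts (smaller cohorts get larger planted r, echoing the observation
that small immune-distinctive cohorts like thymoma show the strongest
coefficients); MBNL2 slightly negative everywhere, MBNL3 weakly positive;
the remaining ~1,940 genes null. Positive planted effects are sized so the
expected t-statistic exceeds ~5 in every cohort, making the 27-of-29
recovery stable across seeds rather than resting on borderline power.

What the preset does *not* emulate: gene–gene covariance beyond the single
factor, batch or purity effects, cohort-specific expression baselines, or
a realistic continuum of gene–infiltration correlations — real
transcriptomes have thousands of genes with intermediate correlations, so
percentiles here are computed against a mostly-null background and genes
with even tiny planted loadings rank higher than they would against real
data. Recovery of the planted conditions therefore demonstrates the
pipeline's correctness, not properties of any real cohort.

**Screen.** Guides start at equal expected abundance; under selection each
guide's abundance is multiplied by its gene's survival factor and the
library is rescaled to a fixed size. Counts are gamma-Poisson with one
shared dispersion (default 0.1, a typical overdispersion for pooled
screens), 4 guides per gene, 10⁷ reads per arm. Replicate structure,
guide-efficiency variation and copy-number effects are not modelled.

## Numerical choices

- Pearson r is computed vectorised (one centred matrix product per
  cohort); values within 10⁻¹² of ±1 are snapped to ±1 with p = 0, since
  beyond that the t-transform is numerically meaningless.
- All writers emit TSV at 6 significant digits; round-trips are identity
  to that precision. Rank tables, tercile labels and gene orderings break
  ties on identifiers so every output is byte-reproducible from
  config + seed.
- Simulator randomness comes from `numpy.random.default_rng(seed)` per
  call; no global state. The acceptance script derives all of its seeds
  from its `--seed` argument, and reports the melanoma-cohort correlation
  as a mean over 20 replicate cohort draws to shrink its ~0.05 single-draw
  Monte-Carlo error to ~0.01.
- Problem sizes in the tests (e.g. 2,000-gene universes, n = 200–5,000
  samples, 10–20 seeds for calibration checks) are chosen so every
  statistical tolerance corresponds to ≥2–3 standard errors of the
  quantity under test while the whole suite stays fast.

## Known limitations

- Correlation is not causation twice over: the proxy is itself bulk
  expression (infiltrating cells contribute to the tumor's RNA), and no
  covariates (purity, stage, subtype) are adjusted for.
- The DE module is rank-based and pseudocount-dependent; supplementary
  tables produced by count-model pipelines will agree in sign and
  ordering, not in exact adjusted p-values.
- Gene identifiers are opaque case-sensitive strings; no ortholog or
  symbol mapping is attempted between, e.g., mouse screen genes and human
  cohort genes.
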