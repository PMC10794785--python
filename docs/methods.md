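# Methods

This note documents the models implemented in `xydosage`, their
assumptions, the defaults of the synthetic-data generators, and the
numerical choices that matter when interpreting results.

## The dosage model

Somatic human cells carry one active X (Xa); additional X chromosomes are
inactivated (Xi) and Y chromosomes add a small set of expressed genes.
Across karyotypes from 45,X to 49,XXXXY and 49,XYYYY, expression of many
genes — including autosomal genes — shifts by a roughly constant log2
increment per additional chromosome copy, which motivates a linear model
in copy number.

For gene *g* and sample *j* with raw count *y<sub>gj</sub>*:

```
y_gj ~ NB(mu_gj, alpha_g)
log mu_gj = log s_j + beta0_g + betaX_g * nX_j + betaY_g * nY_j + batch_gb
```

where *s<sub>j</sub>* is the median-of-ratios size factor (geometric mean
1 across samples), *nX* ∈ {1..4} and *nY* ∈ {0..4} are total chromosome
counts, and batch is treatment-coded. Reported effects are natural-log
coefficients divided by ln 2: log2 fold change per chromosome copy. The
X covariate is the total X count, not the Xi count; since every sample has
exactly one Xa the two differ by a constant, which the intercept absorbs,
so the per-copy slope is identical — the Xi count is still exposed as a
metadata column for convenience.

Alternative designs reuse the same machinery by swapping covariates:
Chr 21 copies (2 vs 3) with sex constitution and batch; sgRNA target and
cell line for knockdown experiments; log2 repeat depth with population and
lab for the heterochromatin-length model.

Fitting details:

- **IRLS, batched.** The design matrix is shared across genes, so the
  weighted normal equations are solved as a stacked set of p x p systems
  (`numpy.linalg.solve` over a gene-indexed batch). A ridge penalty of
  1e-6 on the normal equations stabilizes separated fits (e.g. a gene with
  zeros throughout one batch); genes whose coefficient updates do not fall
  below 1e-8 within 100 iterations are flagged non-converged and excluded
  from the BH denominator. The linear predictor is clipped at +/-30 to
  avoid overflow.
- **Dispersion.** Per-gene method of moments: fit the mean model at
  alpha = 0 (Poisson), then solve E[(y-mu)^2] = mu + alpha mu^2 with a
  1/(n-p) denominator to correct for fitted parameters, flooring at 1e-8.
  No shrinkage trend is applied; a shrinkage option is deliberately left
  as future work so that reported effects are unshrunken MLEs.
- **Inference.** Two-sided Wald tests against the normal reference, per
  coefficient of interest, with Benjamini-Hochberg adjustment across the
  filtered gene set per coefficient. With ~100 samples the normal (rather
  than t) reference inflates the nominal 5% rate to roughly 5.3-5.5%,
  which is visible in the calibration tests and accepted as a property of
  the model class.
- **Expression filter.** TPM is computed from counts and effective gene
  lengths; a gene is kept if its median TPM is >= 1 in euploid 46,XX *or*
  46,XY samples.
- **Renormalization control.** Because sex-chromosomal expression scales
  with karyotype, size factors could in principle distort autosomal
  effects. The control refits the identical model with size factors
  recomputed from autosomal genes only and reports the per-coefficient
  Pearson r and maximum absolute estimate difference; on data without
  gross sex-linked imbalance the two fits agree to r > 0.99.
- **Saturation bootstrap.** Size-n subsets are drawn without replacement
  by pure simple random sampling (no stratification); each subset reruns
  normalization and fitting from scratch. Subsets in which a coefficient
  of interest has no variation, or the design loses rank, are recorded as
  missing rather than dropped, so the rep count is always auditable.

One caveat on invariances: with a raw-count NB GLM and offset, rescaling a
single sample's counts is absorbed by its size factor only up to the NB
weight change (the sample's likelihood contribution grows with depth).
The effect on estimates is tiny (measured max ~2e-4 log2 units for an
8-fold rescale at typical dispersions) but not exactly zero; the tests
assert near-invariance at that scale.

## Shared-response statistics

- **Set overlap.** Upper-tail hypergeometric probability including the
  observed count, P(X >= k), with an explicit Bonferroni denominator —
  the number of tests is never inferred from context.
- **Effect correlation.** Pearson correlation of per-copy log2 effects
  over an explicit gene set; constant vectors are an error, not an NaN.
- **Weighted Deming regression.** Both effect catalogs are estimates with
  standard errors, so an errors-in-variables fit is required. The
  implementation minimizes the profile objective
  S(a, b) = sum (y - a - bx)^2 / (ystd^2 + b^2 xstd^2)
  over the slope (Brent, closed-form Deming start). This formulation is
  exactly equivariant under swapping the axes together with their error
  SDs (slope -> 1/slope), reduces to the classical closed-form Deming
  solution for constant equal errors, and degenerates to OLS of y on x as
  xstd -> 0 and to inverse regression as ystd -> 0. The slope SE is the
  leave-one-out jackknife and the 95% CI is slope +/- 1.96 SE.
- **Variance explained.** R^2 between two effect catalogs is the squared
  Pearson correlation, with the sign of the association reported
  separately (knockdown effects are expected to run opposite to dosage
  effects for genes activated by the dosed factor). A Deming-residual R^2
  would not be standard and is not used.
- **Category enrichment.** Per-category hypergeometric tests against the
  expressed-gene background, BH-adjusted, significant below FDR 0.05.
  Categories that are empty after intersection with the universe are
  skipped and counted.

## Escape meta-analysis

The allelic ratio (AR) is the lower- over the higher-expressed allele; in
skewed cells it estimates Xi/Xa expression. Two conversions anchor the
dialects: AR = 1/f - 1 for a reported Xa read fraction f (f = 0.95 gives
the 0.0526 threshold), and baseline AR = (1 - skew)/skew for the ratio a
fully silenced gene shows at incomplete skewing.

Each dataset caller applies its published inclusion rule and statistic
(see the module docstring for the five dialects); degenerate t inputs are
resolved by convention and flagged: constant positive evidence is treated
as p -> 0, constant zero evidence as not significant.

Synthesis over informative studies (call != no_data): escape if more than
half vote escape, or at least one votes escape and (two or more vote
escape, or the cross-study average AR is >= 0.1); subject if all vote
subject, or more than half vote subject with average AR < 0.1; genes with
no informative study fall back to the Xi-hybrid-line expression fraction
(escape at >= 22%); everything else is no_call. The average AR is the
unweighted mean of per-dataset mean ARs; for the skew-adjusted dialect the
per-dataset mean AR is the mean excess over baseline clipped at zero,
since the source publications do not state which quantity enters the
average. "More than half" is computed over informative studies only.

## Repeat copy number and karyotype PCA

Windowed depths are GC-corrected by bin-median scaling: ten equal-width
GC bins over the single-copy region's GC range, each bin scaled by
(global single-copy median)/(bin median), with repeat windows corrected
using the single-copy bin factors. This is a deliberately simple,
parameter-free correction; it removes smooth GC bias to |Spearman rho| <
0.1 on the scales simulated. The copy-number estimate is mean repeat
depth over mean single-copy depth — invariant to total sequencing depth
and, because both regions share the bias curve, robust even before
correction when their GC distributions match.

For expression-space placement, normalized counts are transformed with
log2(x + 1) — a monotone, parameter-free variance-stabilizing stand-in
chosen over a dispersion-based transform for transparency; the choice is
recorded in output metadata and is adequate for clustering. Batch is
removed per gene by subtracting batch means and restoring the grand mean.
PCA treats samples as observations over a gene subset (typically the
shared X- and Y-responsive genes); component signs are fixed by making the
largest-magnitude loading positive. The 95% centroid ellipse uses the
covariance of the mean (group covariance / n) scaled by the chi-square
0.95 quantile with 2 df — one defensible reading of "confidence interval
around the centroid"; classification does not depend on ellipse geometry,
only on Euclidean distance to centroids in the first two components, with
ties broken lexicographically and flagged.

## Interval semantics

All intervals are BED-style: 0-based, half-open. A gene's TSS is its
annotated start on the + strand and its annotated end on the - strand.
Promoter windows are [TSS - w, TSS + w) clipped at zero, with w = 1 kb
for promoter binding and 30 kb for hormone-receptor target definitions;
binding requires at least one shared base between a peak and the window.
Any-peak-within-window is used rather than nearest-peak-then-cutoff; for
a pure distance cutoff the two are equivalent. Whether the 30 kb in the
source material meant center-to-TSS or edge-to-TSS distance is not
stated; edge-to-window intersection is used here and documented.

## What the generators emulate (and what they do not)

The synthetic-data module is first-class code: its defaults define the
study conditions the tests run under.

- **Karyotype design.** The lymphoblastoid (106 samples) and fibroblast
  (99 samples) series with their published per-karyotype counts; three
  batches assigned round-robin then shuffled.
- **Effects.** 18% X-responsive, 6% Y-responsive, 4% shared genes by
  default, matching the study's proportions; per-copy effects from
  Normal(0, 0.2) so most responses are below 1.5-fold; shared genes have
  betaY = 0.7 betaX + Normal(0, 0.05), making Y effects smaller on average
  with concordant signs. Batch offsets are Normal(0, 0.1) log2 per gene
  and batch — the study includes batch as a covariate without quantifying
  it, so this magnitude is a convention.
- **Counts.** NB with per-gene dispersion 0.05 by default (the study does
  not publish dispersions; this is a typical bulk RNA-seq magnitude) and
  lognormal(sigma = 0.3) library sizes around 2 million reads — chosen for
  desk-scale speed, since only relative normalization matters.
- **Allelic evidence.** Escape genes draw Xi read fractions from a
  beta-binomial (100 reads, overdispersion 0.02) around their Xi
  expression fraction (uniform 0.15-0.45); subject genes carry exactly
  zero Xi signal, so their observed ARs are exactly zero. This is a
  modeling choice, not an approximation artifact: additive AR noise
  clipped at zero would give every subject gene a strictly positive mean
  AR and force the one-sided t callers to reject, contradicting how the
  published callers behave on real data, where silenced genes yield no
  Xi-allele reads. Consequently the generator does not emulate
  low-level technical leakage of Xi reads; caller specificity against
  such leakage is not probed by these tests.
- **Depth profiles.** Gamma-noise depths (cv ~7%) over uniform GC in
  [0.3, 0.6] with an exponential GC tilt exp(strength (gc - 0.45));
  repeat factors spanning 24-900 emulate the observed polymorphism range,
  with 202.5 as the median-scale default. Real repeat arrays differ from
  the single-copy region in GC composition; the generator uses matched GC
  so the correction's bin-transfer step is exercised but compositional
  extrapolation is not.
- **Peaks.** One fixed-width peak per bound gene, jittered around the
  strand-aware TSS and truncated so the peak stays within the promoter
  window — guaranteeing that round-trip tests recover exactly the
  generating bound set at matching half-width.

Passing tests on these generators demonstrate correctness of the
inference machinery under the stated models, not performance on real
data: real RNA-seq has dispersion trends, confounded batches, and
annotation errors that the generators deliberately omit.

## Problem sizes used by the test suite

The acceptance-style tests run the full 106-sample series with 5,000
genes for parameter recovery, 8,000 genes for calibration/FDR, 3,000 for
the shared-response emulation, and 1,000 genes x 100 bootstrap reps x
four subset sizes for saturation — sizes at which the batched IRLS keeps
the whole suite under a minute of fitting time while leaving Monte Carlo
error well below the asserted margins.
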