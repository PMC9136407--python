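# Methods

## The model

`assocmap` tests, feature by feature, whether the abundance of a microbial
taxon (or any non-negative tabular feature) is associated with clinical
metadata, while comparing how those associations behave across several
candidate model definitions fitted to the same data.

For feature *j* with transformed abundance *y<sub>ij</sub>* in sample *i*,
each candidate model fits

  y_ij = β₀ + Σₖ β_k x_ik + u_{g(i)} + ε_ij

where the x's are the model's fixed variables (categorical variables
treatment-coded against a reference level: one indicator per non-reference
level; continuous variables entered as-is), u is an optional random
intercept per group of a random variable (typically subject ID in a
longitudinal design, so repeated samples from one subject are not treated
as independent), and ε is Gaussian noise. Without random variables the fit
is ordinary least squares with two-sided Wald t-tests on the residual
degrees of freedom — for a single binary effect this p-value is exactly
the pooled two-sample t-test. With random variables the fit is a linear
mixed model estimated by REML (statsmodels `MixedLM`), with two-sided Wald
tests under the normal approximation. We deliberately use the normal
approximation rather than Satterthwaite or Kenward–Roger degrees of
freedom: it is simple and stable, and at the cohort sizes this package
targets (hundreds of samples, >100 groups) the difference is negligible;
test tolerances account for it. One non-converged or singular feature fit
is reported as a `fit_failed` status row and never aborts a batch;
features with zero variance are reported as `skipped_constant`.

All nominal p-values of one model run — every feature crossed with every
tested term — form a single Benjamini–Hochberg step-up family, and the
resulting q-values drive everything downstream. Whether to pool across
*models* as well is genuinely open; we adjust per run, so a model's
q-values do not change when other models are added to a comparison, which
keeps single-model results and multi-model comparisons consistent.

## Preprocessing

1. **TSS.** Each sample's features are divided by their total, yielding
   relative abundances. Samples with a zero total cannot be scaled and are
   dropped with a logged warning.
2. **Abundance filter.** Features whose post-TSS total over all samples is
   *strictly* below 1e-4 are removed (a feature summing to exactly 1e-4 is
   retained — the boundary is read literally).
3. **AST.** x ↦ arcsin(√x), mapping [0, 1] onto [0, π/2] ≈ [0, 1.57079].
   The transform spreads small proportions while keeping zeros at zero,
   which suits sparse, zero-inflated microbiome data. It can be disabled
   per model (`ast_enabled=False` / `--no-ast`) for non-compositional
   inputs.

**Missing metadata.** A sample missing a value in any variable *of the
model being fitted* is excluded from that fit only. It remains in every
detail view as an explicit "NA" category — visible, but contributing to no
statistic — and it is included in fits of models that do not use the
affected variable.

## Variable typing

String columns are categorical. Numeric columns with at most 4 distinct
non-missing values are treated as categorical, 5 or more as continuous;
an explicit kind in the schema file overrides inference. Missing entries
do not count as a level — missingness is handled by the NA contract
above, not by inventing a category at fit time. Categorical levels are
ordered alphabetically (users encode custom orders via prefixes:
`a_never`, `b_sometimes`, `c_always`) and the first level is the default
reference; both the schema and each model can override the reference per
variable. Random variables are always grouping factors regardless of
storage type.

## The comparison matrix

A feature becomes a row of the birds-eye matrix iff at least one of its
q-values in at least one model is strictly below the significance
threshold (default 0.2). All of that feature's entries — including
non-significant ones — are retained, so an association that vanishes when
a covariate enters a model is still visible. Cells a model never tested
(possible when preprocessing flags differ between models) are missing,
rendered as "not tested" rather than "not significant". The heatmap
colors -log10(q) for cells passing the threshold only and leaves the rest
blank.

## Stratified detail views

The detail view of one association shows the fitted y (AST scale iff the
model used AST) against the variable: box plots for categorical x (median
line, first/third quartile box using linear-interpolation quartiles — the
fixed, documented convention that makes box geometry testable), scatter
for continuous x. Unfaceted plots carry the model's q-values as
reference-vs-level brackets, including non-significant ones. Faceting by
another variable replaces model q-values with plain two-sided Welch
t-tests computed within each panel from *all plotted samples* (no
model-based masking); Welch rather than Student because group variances
are not assumed equal. Comparisons are reference-vs-other-level only,
matching the bracket convention; panels follow the facet variable's level
order with "NA" last; groups with fewer than 2 samples are reported
untestable.

## The synthetic cohort generator

`assocmap.synth` emulates the structure of a longitudinal infant cohort:
160 subjects × 6 visits (~2-month spacing with N(0, 0.2 mo) jitter), 50
features, binary disease at 50% prevalence, probiotic use drawn per
subject conditional on disease (P = 0.6 given disease, 0.1 given healthy
— the confounding channel), independent delivery mode, per-visit 3-level
diet, and 2% of subjects with missing probiotic status to exercise the NA
contract end to end.

Latent abundances are built on the AST scale: per-feature baseline ~
U(0.06, 0.12), planted fixed effects, a per-subject random intercept
(SD 0.02) and Gaussian noise (SD 0.03), clamped to [0, π/2], then
back-transformed by sin². Baselines and SDs were chosen once so that (a)
the implied relative abundances are small and compositionally plausible
(~0.4–1.5% per taxon), (b) clamping at zero is rare enough (<1% of
draws) not to bias fitted coefficients at the default sample size, and
(c) planted effects of 0.1 (recovery scenarios) and 0.3 (the confounder
scenario) are comfortably detectable at n = 960 — which is the point of a
test bed.

Planting effects on the AST scale makes the engine's coefficients
directly comparable to ground truth, but only if the analysis-side TSS
step does not re-scale the planted values. The generator therefore adds
an explicit `unassigned` remainder feature completing every sample to a
composition summing to exactly 1 (mirroring the unclassified fraction of
real profiles), so TSS at analysis time is the identity. If planted
values alone ever exceeded the simplex the affected rows are renormalized
as a fallback, which would perturb effects; the default configurations
stay far from that regime. One structural consequence worth knowing: the
remainder feature *truly* absorbs every planted effect with opposite
sign, so it legitimately shows up as associated with the planted
variables — tests and studies treat those associations as true, not
false, discoveries.

What the generator does **not** emulate: zero-inflation, phylogenetic or
ecological correlation between taxa, realistic abundance distributions,
diet trajectories over age, or dropout. Passing tests therefore
demonstrate correctness of the statistical machinery under a Gaussian
AST-scale world, not performance on real 16S data.

## Validation studies (assocmap.studies)

* **Null calibration** — 10 cohorts with no effects and zero subject SD;
  each run's pooled nominal p-values tested against Uniform(0,1) by KS.
  Expected: KS p > 0.01 in ≥ 9/10 runs.
* **Coefficient recovery** — 25 cohorts at default size with effects 0.10
  (disease), 0.10 (diet=formula), 0.004/month (age); the full mixed model
  must recover them with mean absolute error below twice the mean
  reported SE in ≥ 95% of replicates. The per-replicate *mean* across the
  three planted terms is the success unit: individual coefficients hit
  their nominal ~95% 2-SE coverage by construction, so averaging is what
  turns coverage into a stable acceptance property.
* **Confounder shift** — 25 confounded cohorts with a +0.3 probiotic
  effect on one feature; in the model without probiotics the feature must
  be significant on disease (q < 0.2), and adding probiotics must make
  probiotics significant while inflating the disease q, in ≥ 90% of
  replicates.

Replicate counts and cohort sizes (960 samples, 51 features) are the
package's chosen study conditions; they complete in a few minutes on one
core while keeping the binomial noise on the reported rates small.

## Numerical and design choices

* Missing-value tokens on input: empty cell, `NA`, `na`, `NaN`.
* A column mixing parsable numbers with non-numbers is an error naming
  the column and first offending row; all-numeric and all-string columns
  are the only valid kinds.
* Rank-deficient fixed designs are rejected up front with the aliased
  column pair named, rather than silently dropping columns.
* BH q-values for failed fits are NaN and excluded from the family size.
* Result TSVs are written with shortest round-trip float repr and fixed
  line endings, making re-runs byte-identical and re-reads exact.
* Numeric categorical levels render without a trailing `.0` (a column of
  1.0/2.0 shows levels "1"/"2").

## Known limitations

* Wald normal-approximation p-values for mixed models are mildly
  anti-conservative for designs with few groups (< ~30 subjects).
* Crossed random intercepts (≥ 2 random variables) use a single
  all-encompassing group with one variance component per variable; this
  is exact for crossed designs but slower, and only the single-grouping
  path is exercised by the validation studies.
* No interaction terms, random slopes, non-Gaussian links, or
  CLR/ILR-style compositional transforms.
* The abundance filter and AST are global per run; per-model thresholds
  are not supported (only the AST on/off flag is per model).
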