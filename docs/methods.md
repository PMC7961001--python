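# Methods

## Normalization

Two stages, both on the linear scale.

**Size factors.** The median-of-ratios estimator: reference genes are those
with strictly positive counts in every sample; the pseudo-reference for
gene g is its geometric mean across samples; sample j's factor is the
median over reference genes of counts[g, j] / reference[g]. The median of
an even number of ratios is the midpoint of the two central values — stated
explicitly because factors depend on it. If no gene is positive in all
samples the estimator fails with a diagnostic count of zero-containing
genes rather than silently shrinking the reference set.

A consequence of the geometric-mean reference worth knowing: scaling one of
m sample columns by c rescales *every* factor by c^(1/m), so only factor
ratios (and the mean-rescaled matrix) are invariant — the property tests
assert that form.

**Mean rescaling.** Every sample is multiplied by target / mean, where the
mean runs over *all* genes present in the matrix, zeros included, and the
target defaults to 1000. The operation is idempotent and puts cohorts
processed separately on one scale. No log transform is applied anywhere in
the pipeline; all survival and enrichment work consumes the linear
mean-rescaled matrix.

## Signature scores

A hallmark's score in a sample is the unweighted arithmetic mean of the
normalized expression of its member genes found in the matrix. Genes
belonging to several hallmarks contribute to each independently. Sets with
fewer than `min_genes` (default 2) members present are excluded with a
warning listing the missing symbols — a single surviving gene should not
silently impersonate a hallmark. The mean is taken on the rescaled linear
scale deliberately: no z-scoring, no log, no direction weighting. This
matters: a hallmark mixing genes whose gain worsens prognosis with genes
whose loss worsens it will partially cancel, and the score tracks the
hallmark's overall transcriptional activity rather than a risk-oriented
combination.

## The cutoff scan

Candidate cutoffs for a feature are every distinct observed value inside
[Q1, Q3] (quartiles by linear interpolation) that leaves both groups with
at least `min_group` samples (default 1). A fixed grid would miss the
lowest-p split on small cohorts; scanning observed values cannot.

Group convention: low = {x <= cutoff}, high = {x > cutoff}; hazard ratios
are high vs low. Each split's p-value is the score (log-rank) test; the HR
and 95% CI at the selected cutoff come from a single-covariate Cox fit with
Efron tie handling. For a binary covariate every Efron term reduces to four
counts per event time (at-risk and events, per group), so the fit is a
one-dimensional Newton iteration over event times (damped steps, step
halving, |log HR| capped at 15 for monotone likelihoods) and a full scan of
hundreds of cutoffs costs milliseconds. The implementation is verified
against lifelines and against a brute-force maximization of the literal
partial likelihood.

Multiplicity is controlled with Benjamini–Hochberg *within the scan*: the
family is the set of cutoffs for one feature, and the feature is
significant iff the q-value at its best cutoff (argmin p, ties to the
smaller cutoff) is below `fdr_threshold` (default 0.10). An optional
second-stage BH across features per cohort is available
(`across_features_fdr`), since which family the correction should target is
genuinely ambiguous; within-scan is the default. The procedure remains
anti-conservative at the feature level — selecting the best of ~150
correlated tests inflates both the significance rate and the HR estimate —
which is why the test suite measures the realized null rate (about 5% at
q < 0.10 on 500 null genes, versus about 45-50% for the uncorrected min-p
rule) instead of assuming a nominal bound.

Degenerate splits (zero events in one group) keep their log-rank p in the
scan but are flagged, report HR as a one-sided extreme (0 or inf) with the
CI suppressed, and can never be selected as best cutoff while a
non-degenerate alternative exists.

**Multivariate models** enter the feature as the dichotomized group at its
best univariate cutoff, plus age (continuous), stage (ordinal 0-4), sex and
grade (binary), and race (one-hot against the largest category).
Complete-case filtering must leave at least 10 events. Constant and
perfectly collinear design columns are dropped and reported with the
reason. The fit itself is lifelines' CoxPHFitter (Efron), cross-checked
against a brute-force likelihood maximization.

**Kaplan–Meier** curves use the product-limit estimator; the reported
median is the smallest time with S(t) <= 0.5 and is undefined (NaN) when
the curve never reaches 0.5.

## Tumor mutation burden

TMB is the raw per-sample count of qualifying variants; the default
qualifying set is the non-silent MAF classes (missense, nonsense, nonstop,
frameshift and in-frame indels, splice site, translation start). No
per-megabase normalization is applied unless an exome size is supplied
(`tmb_per_mb`), because inventing a target size changes nothing in the
rank-based scan and misleads otherwise. Multiple records for one
sample-gene-class triple all count — a MAF legitimately holds distinct
positions. The burden then goes through the same cutoff scan as expression;
integer ties simply reduce the candidate set.

## Cross-tumor aggregation

The significance matrix holds, per hallmark and tumor, 100 x (significant
member genes) / (evaluable scanned member genes); hallmarks with no scanned
member in a tumor are missing, never zero, with numerators and denominators
retained alongside. Clustering is agglomerative (scipy) with euclidean
distance and average linkage by default — configurable, since the choice is
presentation-level — on either axis; missing cells are imputed as zero for
the distance computation only, with a warning. Dendrograms serialize to
Newick with branch lengths from merge-height differences. The
recurrent-feature table lists features significant in at least
`min_tumors` (default 10) tumor types, sorted by count then best p.

## GSEA

Phenotype labels reuse the survival scan's best cutoff (high iff
expression > cutoff, ties low — the same convention as the scan, so the
GSEA groups equal the survival groups; a cross-module test asserts this).
Genes are ranked by signal-to-noise, (mean_high − mean_low) /
(sd_high + sd_low), each class sd floored at max(0.2 |class mean|, 1e-8);
the floor keeps near-constant genes from exploding the metric and makes its
sign stable. The enrichment score is the signed extremum of the weighted
Kolmogorov–Smirnov running sum with weight exponent p = 1: hits add
|metric|^p normalized by the summed hit weights, misses subtract
1/(N − Nh). If every hit metric is exactly zero the hit weights fall back
to equal increments. A magnitude tie between the positive peak and the
negative trough (within 1e-9) resolves to the positive peak so the sign is
deterministic. Significance uses phenotype permutation (class sizes
preserved) with the add-one, same-sign estimator
p = (1 + #{same-sign, |ES_perm| >= |ES|}) / (1 + #same-sign), which cannot
return zero and is uniform under the null (verified by simulation at the
5% level over independent replicates).

## Synthetic data

The generators emulate the statistical structure the analysis assumes, and
only that:

- **Counts**: negative-binomial via the gamma-Poisson mixture with
  mean = size_factor(sample) x base_expression(gene) and dispersion alpha
  (variance mu + alpha mu^2; alpha = 0 gives the Poisson limit). Base
  expressions are log-uniform over (5, 5000) by default so quartile-based
  cutoffs are well populated; size factors uniform over (0.5, 2).
- **Survival**: exponential event times with hazard
  baseline x prod(HR^[x > planted quantile cutoff]) — constant baseline, so
  proportional hazards holds by construction. Effects are planted on the
  normalized (mean-rescaled) expression, the scale the scan consumes.
  Censoring is independent exponential with its rate solved by Brent's
  method so the expected censored fraction hits the target; the realized
  fraction is within 5 points of target on average for n >= 200. Baseline
  hazard defaults to 0.02 events/month (median survival around 35 months,
  a mid-range solid-tumor cohort).
- **Covariates**: sex, race, stage and grade categorical, age normal
  (62 +/- 11, floored at 18) — independent of survival unless planted,
  which is what the multivariate collapsibility test relies on.
- **Mutations**: each (sample, gene) mutates independently with its gene's
  probability; classes drawn from a configurable mix that includes silent
  classes so the non-silent filters are exercised.

One global seed; every generator derives its own stream via
SeedSequence(seed, stream_tag), so a whole cohort is reproducible from one
integer and generators can be called in any order.

What the generators do *not* model — and therefore what passing tests do
not establish about real data: between-gene correlation, batch effects,
copy-number-driven expression, non-proportional hazards, informative
censoring, and covariates correlated with expression. Recovery rates
measured here are upper bounds on what identically-sized real cohorts would
give.

## Problem sizes and numerics

The test suite and the acceptance script use: 200 random small instances
(n <= 20) for Cox-oracle agreement at 1e-6 relative tolerance; a fixed
random suite of p-vectors up to length 12 for BH at 1e-12; 50 replicates of
n = 400 / 30% censoring / HR 3 at the 0.6 quantile for recovery; one
n = 300 cohort with 500 null genes for calibration; 500 independent
replicates for GSEA null uniformity (200 permutations each); and a
two-tumor demo of 300 samples x 500 genes for byte-level reproducibility.

Numerical choices: Newton convergence at |grad| < 1e-10 with step damping
to +/-2 and halving on likelihood decrease; quartiles by linear
interpolation (numpy default); ties at minimum p go to the smaller cutoff;
BH via statsmodels; all writers emit '%.10g' floats, UTF-8, tab-separated,
deterministic row order, so identical configurations produce byte-identical
outputs.

## Known limitations

- The bundled `example_hallmarks.gmt` is a synthetic illustration keyed to
  the synthetic gene ids; real analyses must supply a real hallmark
  catalog as GMT.
- Gene identifiers are opaque symbols; transcript-to-symbol annotation is
  out of scope (an optional two-column mapping can be applied at load).
- No proportional-hazards diagnostics, time-varying covariates or competing
  risks.
- The feature-level error rate of the best-cutoff procedure is not nominal
  even after within-scan BH (see above); across-feature BH is available but
  the anti-conservativeness of cutoff selection itself is inherent to the
  method.
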