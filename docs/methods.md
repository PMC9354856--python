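# Methods

## Scope and data model

raidkit models a paired toxicogenomics design: the same substances profiled
in vivo (rat liver, 3 replicates per group) and in vitro (primary
hepatocytes, 2 replicates per group), each cell carrying a MAS5-scale signal
and an A/M/P detection call, plus a numeric chemical descriptor table. All
matrices are substances × features, exchanged as TSV with a leading
`substance_id` column. Fold changes are ratios of treated to control group
means; all modeling happens on the log2 scale, with the ratio view derived.
Gene identifiers are opaque strings; mapping probes to symbols is out of
scope.

## Fold-change reliability adjustment

Differential-expression calls from small-replicate microarray designs are
noisy, so fold changes judged unreliable are shrunk toward 1 before any
model sees them. Per cell we compute a Welch (unequal-variance) t-test on the
log2 signals — the test is configurable in principle, and the choice of log2
inputs is a package convention — the count of Absent calls among treated
replicates, and an all-calls-Absent indicator. Exactly one rule applies, the
most severe:

1. calls all Absent in both groups of both data sources → value set to 1;
2. p > 0.1 → increment × 1/4 (1.4 → 1.1);
3. treated Absent count ≥ threshold (2 of 3 in vivo, 1 of 2 in vitro) or
   0.05 ≤ p ≤ 0.1 → increment × 1/2 (1.5 → 1.25);
4. otherwise unchanged.

Down-regulated cells (F < 1) are shrunk in reciprocal space,
F′ = 1/(1 + (1/F − 1)k), so the rule is symmetric in the sign of log2 F; the
adjustment is a contraction toward 1 on the log scale and monotone in F for a
fixed rule (both property-tested). An undefined p (zero variance in both
groups with equal means, possible in degenerate or noiseless data) skips the
p-based rules rather than counting as large.

Rules are applied without compounding because the severity ladder already
encodes the evidence hierarchy; applying half then quarter would double-count
one noisy measurement.

## Sample weights and gene filtering

Training samples are weighted by response magnitude m = max(F, 1/F): w = 2
for m ≥ 4, w = 1.5 for m ≥ 1.5, else 1. Using the magnitude makes
down-regulation count symmetrically; thresholds are applied to the adjusted
in vivo target values. Genes with fewer than 10 substances at m ≥ 1.5 are
dropped — rarely-responsive genes give a 5-fold CV almost no signal rows per
fold. Both thresholds are exposed as parameters.

## Descriptor curation and normalization

Curation drops, in order: columns with any missing value, constant columns,
then — scanning left to right — any column whose |Pearson r| with an
already-retained column exceeds 0.95 (the earlier column survives; the greedy
order makes the result reproducible and idempotent). Each retained column
then gets the best normalizing transform among Yeo–Johnson (always
applicable), Box–Cox and log10 (strictly positive columns), square root
(nonnegative), arcsine of the square root (values in [0, 1]) and identity,
chosen to minimize a Pearson chi-squared goodness-of-fit statistic of the
standardized transformed values against N(0, 1) with ⌈2·n^(2/5)⌉
equiprobable classes — deterministic and table-free. The fitted pipeline
(chosen transform, its parameters, post-transform mean/sd) is stored with the
model bank and replayed verbatim on new substances.

A caveat worth knowing: on a column that is already normal, the Yeo–Johnson
shape parameter is weakly identified, so its MLE can wander from 1 and the
"best" transform then warps the column slightly. This is inherent to
best-transform selection at modest n, and it is why even noiseless synthetic
recovery is not exactly R² = 1 (see below).

## The per-gene weighted elastic net

Each retained gene's in vivo log2 fold change is regressed on a feature frame
of normalized descriptors plus the adjusted in vitro log2 fold changes of
*all* retained genes (column names `invitro:<gene>`). Feeding every in vitro
gene to every model, rather than only the same gene, lets the penalty decide
which in vitro signals matter; a `same_gene` mode is available. The objective,
with per-substance weights w and features standardized internally (training
mean/sd stored in the model):

(1/(2Σw)) Σᵢ wᵢ(yᵢ − b0 − xᵢᵀb)² + λ(α‖b‖₁ + ((1−α)/2)‖b‖₂²)

* **Grid.** α ∈ {0, 0.1, …, 1}; per α a 100-point λ-path log-spaced from the
  data-derived λ_max (smallest λ zeroing all coefficients; α floored at 0.001
  in that formula only, to anchor the path) down four decades.
* **Cross-validation.** 5 substance-level folds drawn once per gene from the
  bank seed plus the gene index, shared across the whole grid; fold error is
  the weighted MSE.
* **Selection.** α at the global CV minimum, then the largest λ whose CV-MSE
  is within one standard error of the minimum (the glmnet `lambda.1se`
  convention), falling back to the exact minimizer with
  `selection_rule="min"`. The 1se default trades ~0.3% of held-out R² for
  markedly sparser, better-identified supports — on the default synthetic
  study the mean support-recovery Jaccard rises from 0.29 to 0.60 — which is
  what the in vitro importance ranking and any biological reading of the
  coefficients rely on.
* **Solvers.** Coordinate descent (`sklearn.linear_model.enet_path`) on
  sqrt-weight-rescaled, weighted-centered data, which is algebraically the
  weighted objective above; the α = 0 column uses the exact closed-form
  weighted ridge via SVD, one decomposition per fold covering the whole
  λ-path. Both routes are verified in tests against independent closed-form
  solves.
* **Degenerate targets.** A zero-variance y yields an intercept-only model
  flagged `degenerate`.

A trained bank stores, per gene: standardized-scale coefficients,
(α, λ), CV error, feature means/sds, plus bank-level training medians of
every in vitro feature and the full descriptor pipeline. Banks serialize to a
schema-versioned JSON document with repr-precision floats, so a round trip is
bit-exact and diffs are human-readable.

**Prediction.** New substances pass through the stored descriptor pipeline;
missing in vitro values (per substance, per gene, or the whole block) are
imputed with the training medians; output is the predicted in vivo profile on
both log2 and ratio scales.

**In vitro importance** of a gene's model is
Σ|b_j| over in vitro features / Σ|b_j| over all features, on the
standardized-coefficient scale, 0 when all coefficients are zero. "Importance"
has no canonical definition for elastic nets; this ratio is a package
convention, chosen because standardized magnitudes are comparable across
blocks, and is bounded in [0, 1].

## PCA and read-across analytics

PCA is SVD-based on column-centered data (expression matrices unscaled;
descriptor matrices arrive already normalized). Components are capped at
min(n − 1, p); signs follow a fixed convention (each loading column's
largest-magnitude entry positive) so quadrant assignments reproduce across
backends. Quadrant rankings use strict sign membership — a gene with a zero
loading on PC1 or PC2 belongs to no quadrant — ordered by loading length
√(l₁² + l₂²) with gene-id tie-breaks. PC-related gene sets are the union of
top-30 and bottom-30 signed loadings on PC1 and PC2 (≤ 120 genes), and the
Venn partition over such sets from {in vivo, predicted, in vitro} counts
every exclusive region.

External substances are *projected* onto the training PCA ((X − center) ·
loadings) rather than refit, keeping the training geometry and quadrant
interpretation fixed; refitting remains possible by calling `fit_pca` on a
concatenated matrix. Biosimilar neighbors are ranked by Euclidean distance in
the (PC1, PC2) plane, ties by substance id, query excluded. Per-class 95%
covariance-ellipse parameters (centroid, semi-axes, orientation) are emitted
numerically; no plotting is required for correctness.

**QIVIVE RMSE.** To compare sources with different dispersion, each source's
log2 matrix is z-normalized over all its entries pooled (per-gene
normalization is a config alternative); then per gene RMSE across substances
is computed for predictions-vs-in-vivo and in-vitro-vs-in-vivo, and the two
per-gene RMSE samples are compared with Welch's t-test. The per-gene unit of
analysis matches the gene-scoped contrast the evaluation is about; the
`invitro_important` scope keeps genes whose model places nonzero weight on
the in vitro block.

**PLS-DA.** A minimal 2-component NIPALS PLS regression
(scikit-learn `PLSRegression`, unscaled) on a 0/1 toxicity response,
stratified 70/30 split from a seed, class called at 0.5, accuracy reported on
the held-out 30%. This is deliberately minimal — a sanity check that toxic
and non-toxic substances separate in a supervised projection, not a tuned
classifier.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, on the
log2 scale throughout:

* descriptors D ~ N(0, 1), with planted near-duplicate columns (|r| > 0.95)
  and constant columns to exercise curation;
* a sparse map A (density 0.1, effects N(0, 1)) sends descriptors to in vitro
  log2 fold changes plus N(0, 0.1²) noise; every gene is guaranteed at least
  one effect;
* in vivo log2 fold changes are D·B + c ⊙ (realized in vitro signal) +
  N(0, 0.1²), where B is an independent sparse map and c is nonzero only for
  a designated *in vitro-driven* gene subset (|c| ≈ 1, random sign) — for
  driven genes the in vitro measurement carries information descriptors
  cannot supply, because it includes the realized in vitro noise;
* replicate signals: per-gene baselines ~ 2^N(7, 1) (MAS5-like scale),
  control = baseline·2^ε, treated = baseline·2^(fc + ε), ε ~ N(0, 0.1²),
  with n = 3 in vivo and n = 2 in vitro; Absent calls are drawn at rate 0.05,
  logistically enriched at low absolute signal so the flag-based rules engage
  realistically;
* toxicity labels threshold a latent linear score of the true in vivo profile
  at the 60th percentile (40% toxic, close to the 49/115 split of the bundled
  reference class table), giving PCA/PLS-DA planted structure to find.

Defaults — 80 training substances (+40 held-out from the same maps), 20
genes, 8 driven, 30 descriptors, effect sd 1.0, noise sd 0.1, seed 7 — are
the package's canonical study conditions and are what the recovery tests use.
Randomness is split into purpose-keyed streams (`default_rng([seed, k])`) so
the ground-truth maps and every training row are invariant to the
evaluation-only choice of test-set size.

What the generator does **not** emulate: real descriptor marginals (alvaDesc
columns are skewed and heavy-tailed; here they are normal, which makes the
normalization stage nearly a no-op and slightly flattering), pathway-level
gene correlation, probe-level artifacts, dose/time structure, and any
chemistry. Passing recovery tests therefore demonstrates pipeline
correctness — preprocessing fidelity, estimator consistency, leakage-free
evaluation — not field performance on TG-GATEs-scale data.

A hand-built 6 × 4 worked example (`worked_example_fixture`) pins every
adjustment branch, both weight thresholds, the gene-filter boundary and a
correlated descriptor pair to exact expected values embedded in code.

## Numerical choices and degenerate inputs

* Elastic-net coordinate descent: tol 1e-6, max_iter 5000; equivalence with
  per-λ weighted fits verified at 2e-5.
* Ties in CV selection resolve toward larger λ (path order) and the earlier
  grid α; rank ties in gene lists resolve by gene id — every ranking in the
  package is deterministic.
* Fold-change TSVs are written at %.17g and parsed with round-trip float
  precision, so file round trips are bit-exact.
* Standardization uses sd with one delta degree of freedom; constant feature
  columns get sd 1 (their coefficients are structurally 0).
* Welch tests on identical samples return t = 0, p = 1 by convention;
  zero-variance groups yield an undefined p that the adjustment treats as "no
  p-evidence".
* PCA on a constant matrix, curation with < 3 substances, PLS-DA with one
  class, prediction with missing descriptor vocabulary: all hard errors
  naming the offending input.

## Problem sizes used by the tests and acceptance checks

The recovery suite trains the default 20-gene bank (80 substances, 50
features per model, full 11 × 100 grid, 5 folds) in roughly a minute on one
CPU, a noiseless variant of the same size, and three 12-gene studies for the
importance-ranking property; unit tests use 15 × 5 or smaller oracle
problems. The full test run completes in a few minutes.

## Known limitations

* The noiseless pipeline does not recover truth exactly (per-gene R² ≈
  0.996–1.0): best-normalizing-transform selection on finite samples warps
  already-normal descriptor columns slightly (Yeo–Johnson λ̂ has wide
  sampling variance near normality), an inherent property of the
  normalization stage.
* In vitro importance confounds genuine in vitro dependence with
  descriptor/in vitro collinearity: a non-driven gene can borrow an in vitro
  column that proxies its descriptor signal. The driven set still dominates
  clearly in expectation.
* With α selected at 0 (ridge) a model's support is dense and
  support-recovery metrics for that gene are uninformative.
* Field-scale results (≈1,600 gene models trained on TG-GATEs expression
  data with commercial alvaDesc descriptors) require those external
  resources; nothing here claims to reproduce such numbers, only the method
  and its desk-scale behavior.
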