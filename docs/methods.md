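# Methods

## Desirability mapping functions

Each criterion maps a measured variable x onto a desirability d ∈ [0, 1]
with one of six shapes. The four numeric piecewise shapes follow the
Derringer–Suich convention: plateaus at `des_min` / `des_max` outside the
cut points, and between adjacent cuts a linear ramp raised to a curvature
exponent `scale`:

- **high** (large values desirable):
  d = des_min for x ≤ cut1; des_max for x ≥ cut2; otherwise
  des_min + (des_max − des_min)·((x − cut1)/(cut2 − cut1))^scale.
- **low**: the mirror image (des_max below cut1, des_min above cut2).
- **central**: four cuts; des_max plateau on [cut2, cut3], des_min outside
  [cut1, cut4], ramps between.
- **ends**: the reflection of central — the natural shape for bidirectional
  log fold-changes. With des_min = 0, des_max = 1 and scale = 1,
  d_ends(x) = 1 − d_central(x) exactly.
- **categorical**: a finite label → desirability map with an optional
  default (or an error for unmapped labels). Labels are matched exactly and
  then by string form, so integer 0/1 flag columns match "0"/"1" keys from
  YAML configs.
- **sigmoid**: a smooth logistic alternative to the monotone shapes,
  d = des_min + (des_max − des_min)/(1 + exp(−steepness·(x − midpoint))),
  so d(midpoint) is halfway between the bounds and the sign of `steepness`
  sets the direction.

Parameter meaning and defaults: cut points are in data units and are the
analyst's statement of "good enough" and "unacceptable"; `des_min` defaults
to 0 (a hard filter) but a small positive floor (we use 0.1–0.2 for soft
criteria) deprioritises instead of excluding — useful when evidence such as
database annotation may be incomplete; `scale` defaults to 1 (straight
ramps), values >1 make a criterion harder to satisfy. Cut points may be
given as quantile placeholders (`q:0.25`) resolved from the scored column at
apply time; this expresses "top 10% gets maximum desirability" declaratively
and is deliberately *not* an optimisation of cut points.

Numerical conventions, chosen for continuity and testability:

- at a cut point exactly, the adjoining plateau value applies (the ramp and
  the plateau agree there, so the function is continuous);
- degenerate coincident cuts give a right-closed step: x ≥ cut takes the
  large-x side's value, so a "p < 0.05" style threshold behaves
  conventionally (p = 0.05 is excluded);
- missing inputs give missing desirabilities, never 0 — a 0 means "observed
  and unacceptable" and would wrongly annihilate the overall desirability;
  missingness is resolved at aggregation by weight renormalisation;
- infinite inputs take the corresponding plateau value, since log-ratio
  columns can legitimately contain ±inf.

## Aggregation

The overall desirability is the weighted geometric mean
D = exp(Σ wᵢ ln dᵢ / Σ wᵢ) over criteria with wᵢ > 0 and dᵢ observed.
Implementation choices:

- computed in log space and exponentiated, then clamped into [0, 1] against
  rounding overshoot;
- dᵢ = 0 with wᵢ > 0 short-circuits to D = 0 before any logarithm is taken,
  so no −inf arithmetic can leak into neighbouring rows;
- wᵢ = 0 is a true off switch: the criterion is excluded even if its d is 0;
- missing dᵢ are excluded together with their weights — equivalent to
  renormalising the observed weights to sum to one, so observed criteria
  keep their pairwise ratios (`effective_weights` exposes this
  renormalisation directly);
- a row with no observed, positively weighted criterion is missing (NaN),
  not 0.

Hierarchical fusion applies the identical rule one level up: experiment
overall-D vectors are outer-joined by feature ID, combined with experiment
weights, and features absent from an experiment are treated as missing
there. An `evidence_count` column reports the number of experiments with an
observation per feature. Only weight ratios matter at both levels; the
tests assert scale invariance to machine tolerance.

## Ranking pipeline

`apply_criteria` produces the per-feature, per-criterion desirability
matrix; `rank_features` adds overall D and a 1-based rank. Deterministic
choices where the method itself is silent:

- ties in D are broken by ascending feature ID under a stable sort, so runs
  are bit-reproducible;
- selection by threshold is strict (D > t); top-k clamps k to the table;
- comparison ranks (rank by a single column, e.g. p-value, after optional
  keep-prefilters such as "mean expression ≥ 6 and SD ≥ 0.25") use the
  "min" tie method; filtered-out features get a missing rank;
- column names are matched case-sensitively; a mismatch is a configuration
  error naming the criterion and column, never a silent drop.

Config validation collects every problem before failing, so a six-criterion
file with three mistakes reports all three at once.

## Sensitivity analysis

Cut points and weights are judgement calls; the sensitivity analysis
quantifies how much the final list depends on them. Each targeted parameter
is jittered uniformly — weights relatively (their meaning is a ratio), cut
points absolutely in data units — and the full ranking is recomputed per
draw. Reported statistics: Jaccard overlap of each draw's top-k with the
baseline top-k (k defaults to the baseline selection size), Spearman
correlation between draw and baseline overall desirabilities, and
per-feature selection frequency. Draws that violate an invariant are
repaired (cuts re-sorted, weights/bounds clamped) and counted, rather than
discarded, so coverage is not biased toward mild perturbations. The uniform
deviates are drawn from the plan's seed independently of the magnitudes,
which couples plans of different magnitude on the same seed and makes
"larger jitter never improves worst-case overlap" a checkable comparison.

## Synthetic data generator

The generator emulates the statistical shape of a processed two-group
expression study, which is what the ranking consumes:

- baseline log2 expression: `baseline_loc + Gamma(shape 2, scale
  baseline_spread)`, default 4 + Gamma(2, 1.5) — right-skewed, mean ≈ 7,
  mostly within the 4–14 log2-intensity range typical of arrays;
- `prop_de` (default 0.1) of features shifted ±`effect_size` (default 2.0
  log2 units) in group 2, signs balanced;
- i.i.d. Gaussian sample noise (`noise_sd`, default 0.5 log2 units) plus a
  shared latent "proliferation-like" factor loading a `marker_corr_structure`
  fraction of features, with one designated marker feature, so a marker
  correlation column exists;
- per-feature columns computed from the simulated matrix exactly as a
  practitioner would: log fold-change, mean expression, Welch two-sample
  p-value, SD, Pearson correlation with the marker feature, and a binary
  annotation. A Welch test is used because any valid p-value source
  suffices to exercise the ranking; moderated (empirical-Bayes) tests are a
  property of upstream analysis, not of this package.

A `prop_planted` fraction of the DE features is *planted*: constructed to
satisfy every criterion at once — annotated, unloaded on the latent factor,
baseline drawn from the upper tail (85th–99.5th percentile) of the baseline
distribution. Planted features are the recovery ground truth.

Two named condition sets:

- `strong_signal_config`: n = 10,000 features, 10 samples per group, effect
  2.0, noise 0.5 — a 4σ per-sample separation. Background annotation is set
  to 0 here so the annotation criterion is exclusive to the planted subset.
  This is what makes "100% recovery" a well-posed oracle: with background
  annotation, chance-annotated DE features are legitimate look-alikes that
  can tie or beat the weakest planted feature, which reflects real data but
  measures the generator, not the ranking. Under these conditions every
  planted feature's overall D exceeds every non-planted ceiling
  (0.2^(w_annot/Σw)) by construction, so recovery is deterministic up to
  extreme sampling tails.
- `null_config`: no effects, no planted features, and the latent factor off.
  Latent structure leaves p-values uniform only marginally while correlating
  them across loaded features, which inflates the variability of any
  single-run calibration statistic; an exchangeable i.i.d. null is the
  distribution a KS uniformity check actually tests.

What the generator does not emulate: probe-level artefacts and
normalisation effects, heavy-tailed or heteroskedastic noise,
gene–gene correlation beyond the single latent factor, and moderated
variance estimation. Passing recovery benchmarks therefore demonstrates the
correctness of the ranking machinery under known ground truth, not
performance on any particular real data set.

## Problem sizes and runtimes

The test suite and the acceptance script use 10,000 features × 20 samples
for calibration and recovery runs (matching the scale of a typical array),
10,000 random specs/rows for the function-law and oracle checks, and
800–2,000-feature tables with 15–20 Monte Carlo draws for sensitivity
checks — sizes at which every check is exact or tightly bounded while the
whole suite runs in seconds.

## Known limitations

Desirability scores are preferences, not probabilities: there are no
p-values or intervals attached to D, and the method will not discover
criteria — it formalises the ones the analyst states. Results depend on the
chosen cut points and weights; that dependence is explicit (the provenance
record stores the fully resolved criteria) and measurable (the sensitivity
module), but not eliminated. Since functions can be tuned to favour
particular genes, the intended workflow is criteria → ranked list →
validation, never the reverse. The accession-validation command
(`validate-gds1329`) requires a locally prepared table; downloading and
differential-expression preprocessing are outside this package's scope.
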