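# Methods

## Measurement model

All item-response computation uses the Rasch partial credit model (PCM):
unidimensional, unit discrimination for every item, polytomous categories
scored 0..K. The probability of category k at ability θ is proportional to
exp(Σ_{j≤k}(θ − δ_ij)), with the empty sum zero for k = 0. Effective
thresholds decompose as δ_ij = δ_i + τ_ij: an overall item difficulty plus
centered step deviations, matching the two-part layout of the packaged
calibration table. A dichotomous item is a one-step item, so its single
threshold equals the overall difficulty when the step is 0.

Item scoring starts at 0 (a dichotomous item scores 0/1); this is implied
by the dichotomous special case of the category-probability formula and by
the 0/1 coding of the gender item.

Numerics: probabilities are computed by softmax over the cumulative
logits, which is overflow-safe for |θ| well beyond the engine's working
range (tested to |θ| = 40). Item information is the conditional response
variance, identical to the derivative of the expected score in θ (tested
against a central finite difference at step 1e-5, tolerance 1e-6).

### The packaged item bank

The 30-item skin-cancer risk bank ships as CSV (`item_id`, `text`,
`overall_difficulty`, `step1..step4`, `NA` for absent steps). Structural
invariants (contiguous ids, 1–4 steps, finite values) are enforced at
load. Step centering — polytomous steps summing to ~0, dichotomous step
exactly 0 — is *not* enforced, because six published items deviate from it
(items 9, 11, 14, 15, 16 by up to 1.04 logits; item 12's single step is
0.99, equal to its overall difficulty). `check_centering` reports these as
diagnostics. The threshold decomposition is applied uniformly, so item
12's effective threshold is 1.98 logits. Item 6 has disordered step
thresholds; the PCM tolerates this and the values are used as printed.

## Cohort simulation

The virtual cohort emulates the study conditions: n = 1000 respondents,
abilities θ ~ Normal(0, 1) logits, responses sampled from the PCM at the
true θ, binary cancer label = 1 iff θ ≥ 0.88 logits (boundary inclusive,
fixed for determinism). Labels derive from the *true* simulated ability,
not a re-estimated measure — the only self-contained reading of a cutoff
applied to simulated data. The positive fraction is therefore the standard
normal tail beyond 0.88, about 18.9%.

What the generator does *not* emulate: local dependence between items,
misfit to the PCM (every simulated respondent is model-conforming),
missingness other than CAT-induced, and any covariate structure of a real
survey population. Passing benchmarks therefore demonstrate internal
consistency of the pipeline under the model's own assumptions, not
real-world classification accuracy.

Hold-out splitting is a seeded uniform shuffle, 70:30 by default,
unstratified (a plain random split); k-fold is stratified by label by
default, mirroring the common cross-validation harness convention.

## Adaptive testing engine

- Initial θ = 0; the first item is drawn uniformly from the bank (seeded).
- One capped Newton–Raphson step per administered item
  (θ_{m+1} = θ_m + Σ(O − E)/ΣVar evaluated at θ_m), with full iteration to
  convergence only for the final estimate. A between-item full-convergence
  mode is available (`iterate_between_items=True`); the step-wise default
  produces the familiar smooth provisional-θ trace.
- Safeguards: step capped at 1 logit, θ clamped to [−6, 6]. The raw score
  equation has no finite root for perfect/zero patterns; the cap-and-clamp
  combination (the standard Winsteps-style guard) makes every session
  terminate. Both safeguards can be disabled to study the textbook
  formula.
- Item selection: argmax of item information at the current θ over
  unadministered items, ties to the lowest item id.
- Stopping (dual rule): primarily SE < SEM, with SEM = SD·√(1 − rel) =
  0.469 for SD 1.0 and Cronbach α .78; secondarily |Δθ| < 0.05 logits once
  at least 5 items are administered (the two published stop descriptions
  are not reconciled with each other, so both are implemented with the SEM
  rule primary); bank exhaustion as the terminal fallback. The
  last-5-steps trajectory-flatness correlation is exposed as a diagnostic
  only — no stopping threshold for it is established.
- Imputation: after stopping, unanswered items receive their expected
  scores at the final θ, yielding a complete real-valued 30-vector for
  classification.

### Person fit

Z = (O − E)/√Var per administered item; outfit MNSQ = mean Z², infit
MNSQ = Σ(O−E)²/ΣVar, both evaluated at the final θ. The df-adjusted mean
square is v = outfit·n/(n−1) with df = n−1, and the default t transform is
t = ln(v) + v − 1, which reproduces the published worked example
(outfit 0.52 over 9 items → v = 0.585, t = −0.95) with unit scale; a
Wilson–Hilferty cube-root standardisation is available via
`t_transform(..., method="wilson_hilferty")` for users who prefer the
classical normalisation. Outfit > 2.0 flags an aberrant pattern.

Under the default stop rule, 200 simulated N(0,1) respondents need about
5–6 items on average (SE of a session with ~5 informative polytomous items
drops below 0.469), and final estimates correlate ≥ 0.85 with the true
abilities — consistent with the √reliability ≈ 0.88 attenuation implied by
α = .78.

## Classifiers

Naive Bayes (Gaussian per feature, variance-floored), k-nearest neighbors
(Euclidean), and unregularised logistic regression (IRLS-type
newton-cholesky solver, max 100 iterations, tolerance 1e-8,
non-convergence surfaced as a warning with the last iterate kept). Fits
are delegated to scikit-learn behind the module surface; features are the
raw item scores (or imputed reals), unstandardised.

KNN defaults to k = 1. The cross-validation harness this package mirrors
uses 1 as its nearest-neighbour default, and k = 1 also reproduces the
characteristic published pattern: near-perfect training metrics under
hold-out (the query row is its own nearest neighbour — the self row is
deliberately not excluded when scoring the training set) alongside a
visibly lower cross-validated AUC once predictions are honest out-of-fold
votes. k is a plain argument everywhere for sensitivity analysis.

## Evaluation

Confusion counts at an operating point; sensitivity, specificity,
precision, accuracy; undefined ratios (zero denominators) are reported as
absent, never as 0.

Two AUC notions are used deliberately:

- **One-point AUC** for hold-out tables: the area under the two-segment
  ROC through the single (1−spec, sens) operating point,
  (1−spec)·sens/2 + (sens+1)·spec/2. This is the printed arithmetic of
  the reference tables (0.83/0.99 → 0.91; 0.70/0.92 → 0.81).
- **Full trapezoidal ROC AUC** for k-fold: computed on pooled out-of-fold
  probabilities (each respondent predicted exactly once), the convention
  of standard cross-validation reports.

CIs use the normal approximation AUC ± 1.96·√(AUC(1−AUC)/N) with N the
evaluated sample (300 for the test split, 1000 for pooled k-fold), bounds
clipped to [0, 1]. Between-model "significant difference" flags mean
non-overlapping 95% CIs — deliberately cruder than DeLong/bootstrap
comparisons, which are out of scope.

**Balanced operating point.** With ~19% positives, a fixed 0.5 threshold
skews sensitivity against specificity. Confusion-based metrics therefore
default to a decision threshold at the midpoint of the two
class-conditional mean predicted probabilities of the set being scored;
this balances sensitivity and specificity in reports and is how the
reference workflow handled imbalance. It is an evaluation-time reporting
choice (the fixed 0.5 threshold is available with `balanced=False`) and
never affects the threshold-free full ROC AUC.

## Per-item effect sizes (forest data)

Each item column is z-scored over the whole cohort (redundant for an SMD
— affine invariance is tested — but it defines the plotted scale), then
Cohen's d with pooled SD between label groups is computed with
SE = √((n1+n0)/(n1·n0) + d²/(2(n1+n0))) and a normal 95% CI. Positive d =
cancer group scores higher. Heterogeneity across the 30 effects is
Cochran's Q with inverse-variance weights, df = 29, p from chi-square —
the natural chi-square heterogeneity test for a forest plot. The exact
estimator behind the reference figure is unstated; pooled-SD Cohen's d is
the standard forest-plot SMD and is the documented choice here.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed or
`numpy.random.Generator`; no global RNG state is used. The CLI expands one
umbrella seed into per-stage seeds via `SeedSequence.generate_state`. The
acceptance script averages the simulation benchmarks over five seeds
derived the same way; five seeds at n = 1000 give Monte-Carlo scatter of
about ±1 AUC point, a sensible precision/runtime balance for a package
check (the whole script runs in seconds). Property tests use 200 simulated
CAT sessions for the consistency check — enough for a correlation
estimate with standard error ~0.02.

## Known limitations

- The published table's exact simulated cohort is not recoverable (its
  seed is unpublished), so simulation benchmarks reproduce magnitudes and
  orderings, not cell values. Our k-fold 1-NN AUC sits at ~0.89 against
  the published 0.85 (whose CI is 0.83–0.87); NB/LR cross-validated AUCs
  (~0.98) match their published values exactly at 2 dp.
- The Gaussian naive Bayes variant is a documented choice; the reference
  implementation's variant (binning vs Gaussian) is not recoverable from
  the available material.
- The engine is strictly unidimensional PCM: no graded-response/2PL/3PL
  models, no exposure control or content balancing, no multidimensional
  CAT.
- Item parameters are consumed as given; calibrating them from raw
  response data is upstream of this package and out of scope.
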