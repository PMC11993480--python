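# Methods

## The score

The Targeted Surgical Score grades six radiographic criteria of
implant placement and fracture reduction after proximal femoral
nailing and sums them to 0–8 points. Two criteria carry up to two
points (tip–apex distance, lag-screw quadrant), four are binary (AP
alignment, lateral alignment, medial and anterior cortical support).
Higher is better; the clinical bands are 7–8 very-low, 5–6 low, 2–4
moderate and 0–1 high risk of mechanical complication.

### Geometric conventions

* **TAD.** Each film's apparent tip-to-apex length is rescaled by
  `d_true / d_apparent` (the known lag-screw diameter calibrates the
  film's magnification) and the two corrected lengths are summed. The
  quantity is therefore invariant to uniform magnification of either
  film, and linear in the apparent lengths. Only ratios of image
  coordinates enter any formula, so coordinates are abstract planar
  units and no pixel spacing is needed.
* **Quadrants.** The femoral head circle is split into three equal
  bands perpendicular to the neck axis, in each plane. The normalised
  position `s ∈ [0,1]` of the screw centre across the head diameter
  selects the band (`s < 1/3`, middle, `s > 2/3`). Boundary values
  (`s = 1/3`, `s = 2/3`) go to the **middle** band: ties favour the
  clinically modal central category and keep the partition exhaustive.
  A screw centre more than `head_radius × tolerance` (default 5%)
  outside the circle is an error; within the tolerance it is clipped,
  since circle-fitting jitter on real films routinely places a
  well-seated screw marginally outside the fitted head.
* **Alignment.** The collo-diaphyseal-angle difference is
  fractured-minus-intact: negative = varus, positive = valgus. Exactly
  0° (neutral) earns the AP point; exactly 10° of valgus does not
  (strict `< 10°`). Any varus scores 0 by default; a configurable
  `varus_tolerance` (default 0°) lets users grade small varus
  differences as neutral if their measurement protocol warrants it.
  Lateral angulation is stored as a magnitude (the 20° threshold is
  applied without sign); exactly 20° scores 0.
* **TAD bands.** `[25, 30)` earns one point and `[30, ∞)` zero; 25 mm
  itself is therefore one point, 30 mm zero.
* **Cortical support.** Negative/neutral/positive may be supplied
  directly (the development study graded it visually) or derived from
  a signed cortex-to-cortex offset with a configurable neutrality band
  (default ±1 mm; the grading literature defines only the categories,
  not a numeric band). Positive means the head–neck fragment cortex
  rests on or medial/anterior to the shaft cortex; the lateral-plane
  sign convention follows the reduction-quality literature and is
  configurable by preprocessing the offset sign.

### Predicted probability

A per-point logistic model `p(t) = 1/(1 + e^{-(β0 + β1 t)})` can
decorate scores with complication probabilities. The published
per-point coefficient is β1 = −0.597; the intercept was not published
and is derived from the reported optimal probability threshold 0.248
at a score of 3: `β0 = logit(0.248) + 3·0.597 ≈ 0.6817`. Everything
downstream treats this intercept as derived, not observed. Scoring
never requires a fitted model.

## Validation battery

* **Logistic fits** are Newton–Raphson MLEs (statsmodels `Logit`,
  tolerance 1e-10, 100 iterations) with SEs from the observed
  information; 95% CIs are Wald (`± 1.96 SE`), matching the symmetric
  published CIs; odds ratios are exponentials. Perfect separation and
  rank-deficient designs raise typed errors rather than returning
  garbage coefficients.
* **ROC** uses the empirical curve over all distinct thresholds. The
  risk marker is the fitted probability when a model is supplied and
  the negated score otherwise — identical rankings for any monotone
  decreasing fit, which a test asserts. AUC is the trapezoid area,
  equal to the tie-corrected Mann–Whitney concordance probability (a
  brute-force pair-counting oracle verifies this on small cohorts).
  The Youden cutoff maximises J = sensitivity + specificity − 1,
  breaking ties toward the more sensitive threshold so the output is
  deterministic on a 9-level score; a probability threshold is mapped
  back to the largest score whose predicted probability still meets
  it. A positive screening call is `score ≤ cutoff`.
* **Hosmer–Lemeshow** groups by predicted probability into deciles of
  risk, with `duplicates-drop` quantile binning so bins tied on a
  single discrete prediction collapse (on a single-covariate score
  model the effective groups are score levels); df = groups − 2. The
  statistic accumulates `(O−E)²/(E(1−E/n_g))`, which covers both
  outcome classes per group.
* **Group comparisons**: Mann–Whitney U with the normal approximation,
  continuity and tie correction (standard large-sample practice) for
  continuous measures; Pearson chi-square for categorical tables, with
  a low-expected-count flag instead of a hard failure. Two-proportion
  z-tests are pooled. All p-values are two-sided and unadjusted, as in
  the source analysis.
* **McFadden R²** is `1 − ll_model/ll_null`; the likelihood-ratio test
  uses df = number of non-intercept covariates. VIF is `1/(1−R²_j)`
  from regressing each covariate on the rest; exact collinearity is
  reported as `inf`.

## Synthetic cohort generator

The generator's defaults are the development-study conditions: n=586,
prevalence 48/586 ≈ 8.2%, and the published per-group structure.

* **Margins.** Trinary sub-scores are moment-matched exactly on
  {0,1,2} by solving `p1 + 2p2 = mean`, `p1 + 4p2 = sd² + mean²`
  (infeasible moments raise an error naming the violated bound).
  Binary sub-scores are Bernoulli(mean); the implied `√(p(1−p))` is
  exposed for cross-checking against the published SDs, which it
  matches within rounding for every published binary margin.
* **Dependence.** The study publishes only marginal sub-score moments
  plus the total-score SDs. Independent margins give total SDs of
  ≈1.52 (complication) and ≈1.28 (non-complication) — far below the
  published 2.22 and 1.56 — so the criteria are substantially
  positively dependent (surgical quality is a common cause). The
  minimal structure reproducing both facts is an equicorrelated
  Gaussian copula per group: latent `z_j = √ρ·w + √(1−ρ)·e_j`
  thresholded through each margin's inverse CDF. ρ is calibrated by
  bisection of the simulated total-score SD against the target
  (tolerance 0.05, 100 000 draws, common random numbers under a fixed
  internal calibration seed, so the calibrated ρ is a deterministic,
  cached function of margins and target: ≈0.44 and ≈0.25 for the two
  groups). The margins pin the total mean, so ρ moves only the spread.
* **Modes.** `distribution_matched` draws the outcome first
  (Bernoulli at the configured prevalence) and sub-scores from the
  outcome group's copula — this reproduces the two published group
  distributions directly. `model_based` draws the mixture component
  and sub-scores the same way but then draws the outcome from the
  per-point logistic model at the total, giving an exactly
  logistic score–outcome relationship for parameter-recovery and
  calibration tests; at the default parameters its realised prevalence
  stays within two percentage points of 8.2%.
* **Back-fill.** Raw measurements are drawn consistently with each
  generated sub-score: TAD, CDA difference and lateral angulation from
  the group's published normal restricted (by inverse-CDF sampling) to
  the half-open band the sub-score implies, with finite upper
  endpoints excluded so boundary scoring is exact; quadrants from the
  group's published frequency table conditioned on the score class,
  with the unpublished remainder spread uniformly over the five
  "acceptable" combinations; a supported cortex is split 50/50 between
  positive and neutral (the split is score-invisible, as both grades
  earn the point). Re-scoring the back-filled measurements reproduces
  the generated sub-scores exactly, by construction and by test.
* **Determinism.** One seeded PCG64 stream drives generation in a
  fixed, vectorised draw order; identical config + seed yields
  byte-identical CSVs. Vectorised single-stream generation was chosen
  over per-record streams for speed at the 100 000-record fidelity
  checks; the reproducibility that per-record streams would buy is
  guaranteed by the fixed draw order instead.

### What the generator does and does not emulate

It reproduces group-wise margins, totals, prevalence, quadrant
frequencies and measurement moments, so tests exercising score rules,
fit machinery, ROC behaviour and calibration on it are informative
about the code and about the published summary structure. It does
**not** reproduce the real joint distribution beyond equicorrelation,
per-score-level complication counts (only published graphically), or
any covariate structure among demographics (the study found no group
differences there, and no signal is simulated). Passing recovery tests
therefore shows consistency of the published summaries with the
implementation, not clinical validity on new patients.

## Problem sizes and test design

Stochastic checks use 100 cohorts of n=586 (the study's size) for
discrimination and cutoff recovery; 100 replicates of n=5000 for
CI-coverage and Hosmer–Lemeshow behaviour, where finite-sample Wald
and binning noise would otherwise dominate; and single 100 000-record
cohorts for law-of-large-numbers fidelity bounds (margin error
< 0.02). The whole suite runs in well under a minute on one core.

## Known limitations

* The published OR 0.551 is the exponential of the *unrounded*
  coefficient; `exp(−0.597) = 0.5505`, so third-decimal comparisons
  against printed ORs use a 0.001 tolerance.
* The logistic intercept, the copula correlations, and the
  within-class quadrant frequencies are derived or calibrated, not
  published; they are flagged as such in the config sidecar and here.
* The Youden cutoff on synthetic cohorts concentrates on 3–4 points
  (median 4) rather than exactly the published 3: the per-level joint
  distribution that fixes the cutoff is not published, and both values
  are consistent with the summary structure the generator matches.
* No image processing: landmark coordinates or scalar measurements are
  the input boundary. Calcar-referenced TAD variants and weighted
  score refinements are out of scope.
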