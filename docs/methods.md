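# Methods

This note documents the models, conventions and design choices behind
`soiltrial`, in the spirit of a statistical package's methods appendix.
It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Trial model

The package targets a randomized complete block fertilization trial on a
continuous cotton system: 5 treatments (CK, CF, M1, M2, M3 — the M
treatments substitute 25/50/75 % of fertilizer nitrogen with organic
manure) × 6 blocks = 30 plots, a seed-cotton yield (kg·ha⁻¹) per
plot-year over a 10-year span, and one final-year measurement of 12 soil
indicators per plot. Yield tables are long format (one row per
plot-year); soil tables are wide (one row per plot). Indicator headers
are resolved through a public alias table (`NO3-N`, `no3_n`,
`nitrate_n`, … all load as `nitrate_n`), because abbreviation
conventions differ between lab sheets and publications. Missing cells
are rejected by default; a permissive mode tags the affected lines for
listwise deletion instead, since silent imputation would change every
downstream statistic.

## Soil quality index

1. **Scoring.** Direction-aware min-max scaling onto [0, 1]. The
   default direction map scores bulk density and pH as *less is better*
   and the ten nutrient/enzyme indicators as *more is better*. Bulk
   density's negative loading on soil function is conventional. pH is
   genuinely ambiguous near neutrality — on the slightly alkaline soils
   this design targets (pH ≈ 7.0–7.3) a lower value is mildly
   favorable, so *less is better* is the default, but the map is an
   explicit argument everywhere precisely because other soils warrant
   the opposite choice (or exclusion). Scoring bounds are computed over
   all 30 plots jointly: a single shared ruler is required for
   cross-treatment comparison. A constant indicator makes min-max
   scoring undefined; it is an error by default, or dropped with a
   logged warning on request.

2. **Weighting.** Indicators are z-scored and the eigendecomposition of
   their correlation matrix taken. The communality of indicator *i* is
   the variance captured by the retained components,
   cᵢ = Σₖ λₖ vᵢₖ² ∈ [0, 1]; weights are communality shares
   Wᵢ = cᵢ/Σcⱼ. Retention defaults to the Kaiser rule (λ ≥ 1) and can
   be a fixed count, a cumulative-variance fraction, or `all` (which
   makes every communality 1 and the weights uniform — a useful
   degenerate check). Eigenvalues below 1e-10 are treated as numerical
   zeros (rank deficiency at n = 30 with correlated indicators) and
   discarded with a logged note. The PCA operates on the z-scored raw
   measurements, not on the min-max scores: communalities are
   conventionally extracted from standardized measurements, and the two
   differ once directions flip signs. `pca_on="scores"` exposes the
   alternative.

3. **Aggregation.** SQI = Σ Wᵢ Sᵢ per plot, hence SQI ∈ [0, 1];
   treatment summaries are mean ± SE over the 6 replicates. Reports of
   SQI on other scales exist in the literature (including ranges well
   above 1 that are impossible under a convex combination of unit-range
   scores); this package stays on the canonical [0, 1] scale of the
   defining formula and leaves any display rescaling to the caller.

## Sustainable yield index

SYI = (Ȳ − σ)/Ymax per yield series. Conventions:

- **Granularity**: computed per plot over that plot's own 10-year
  series, then analyzed across the 6 replicates. A one-way ANOVA on SYI
  (df = 4 between treatments) is only possible with replicate-level
  values; the treatment-mean-series variant is also exposed
  (`treatment_series_syi`) for comparison with aggregate reports.
- **σ** defaults to the sample (n−1) standard deviation; a
  `sd_mode="population"` switch selects n. Sample-σ SYI is never above
  population-σ SYI, and the mode is recorded in the run manifest.
- **Pathologies**: SYI ≤ 1 always, with equality iff the series is
  constant and positive; σ > Ȳ yields a negative SYI, which is returned
  as-is with a warning — clipping would hide dispersion pathologies.
  All-zero series and single-year series are errors.

## Inferential layer

- **ANOVA** is one-way fixed-effects from explicit sums of squares
  (F = MSB/MSW, p from the F distribution). Zero within-group variance
  with non-zero between-group variance is reported as F = ∞, p = 0 with
  a degeneracy flag rather than an exception. Blocks are not modeled as
  a factor, matching the one-way analysis this workflow mirrors; a
  mixed model of the block structure is explicitly out of scope.
- **Assumptions**: Shapiro–Wilk per group and Levene across groups at
  α = 0.05; groups too small (n < 3) or constant are flagged
  not-assessable rather than failed.
- **Letters**: all pairwise comparisons (default Tukey HSD via the
  studentized range; `lsd` gives unadjusted pooled-variance t-tests),
  rendered as a compact letter display by the insert-and-absorb
  algorithm. The display is a deterministic function of the pairwise
  significance matrix: two treatments share a letter iff their
  comparison is nonsignificant at α, and `a` marks the highest mean.
  Tukey is the default because it is the conservative convention for a
  five-treatment family.
- **Correlations**: pairwise Pearson r with two-sided p-values and the
  star map p < 0.05 `*`, < 0.01 `**`, < 0.001 `***`. No multiplicity
  correction is applied by default (matching common practice for these
  descriptive matrices); a `fdr` flag applies Benjamini–Hochberg for
  users who want it. Constant variables are flagged, not fatal.
- **Regression**: ordinary least squares of SYI (and mean yield) on
  SQI; R² equals the squared Pearson correlation (simple-regression
  identity, also asserted in the tests).

## Random-forest importance

Importance of the 12 indicators for plot-level mean yield and SYI uses a
bagged regression forest with out-of-bag (OOB) evaluation — there is no
data to spare for a holdout at n = 30:

- Trees are CART regression trees (`DecisionTreeRegressor`), each grown
  on a bootstrap sample drawn by the package itself so the OOB sets and
  every random draw sit under one seeded generator; ⌊p/3⌋ features per
  split and leaf size 5, the usual regression-forest defaults; 1000
  trees by default.
- **Importance** of predictor *j* is the percent increase of the
  tree-averaged OOB MSE when *j*'s values are permuted within each
  tree's OOB set: 100·(MSEⱼ − MSE₀)/MSE₀. Averaging errors before
  taking the ratio keeps the measure stable when individual trees have
  tiny OOB error. Predictors are processed in a canonical (sorted)
  internal order so results depend only on names and values, never on
  the column order of the input frame.
- **Significance** comes from an explicit response-permutation null:
  the full forest is refit on shuffled responses B times (B ≥ 99) and
  p = (1 + #{null ≥ observed})/(1 + B). The add-one estimator keeps
  p ≥ 1/(1+B) > 0. The null is defined this way so that the printed
  stars are exactly reproducible; opaque importance-permutation
  utilities differ in ways their documentation does not pin down.
- **Fit quality** is OOB variance explained,
  100·(1 − MSE_oob/Var(y)); it can be negative for a pure-noise
  response.

## Synthetic generator

The generator exists so the full analysis is testable without access to
raw trial data; its defaults emulate the published final-year state of
the trial the package models.

- **Anchors** (exact in the defaults, with provenance strings in
  `soiltrial.synthetic.ANCHORS`): control bulk density 1.35 g·cm⁻³
  falling to 1.22 under M3; control pH 7.04 rising to 7.30 under M3;
  CF bulk density +9.74 %; nitrate-N 8.18 → 25.32 mg·kg⁻¹ under CF;
  M1 increases vs control of +99.56 % (organic matter), +90.33 %
  (total N), +156.35 % (NH₄-N); urease +100.00/71.17/32.43 % and
  catalase +62.06/45.62/45.63 % under M1/M2/M3; and the pre-trial site
  panel (organic matter 12.80 g·kg⁻¹, total N 0.61 g·kg⁻¹, alkali-N
  49.00, available P 28.30, available K 191.00 mg·kg⁻¹) used as the
  control's final-year nutrient state (plausible for a decade without
  fertilizer). Cells with no published value — control NH₄-N and
  enzyme levels, and the non-anchored treatment cells — are package
  choices at realistic magnitudes that preserve the published ordering
  claims (M1 leads the nutrient enrichment, CF leads nitrate and bulk
  density, M3 the pH recovery, enzymes respond monotonically in the
  organic share). An organic-fraction interpolation was rejected
  because CF (organic fraction 0) must still exceed the control on
  every nutrient.
- **Yield model**: yield = base + trend·(year − first) + block effect +
  residual, truncated at 0, with the block effect shared across a
  plot's years (a randomized-block field layout) and iid Gaussian
  residuals. Absolute yield levels are NOT published values; the
  defaults (base means 4200/5700/6500/6300/6000 kg·ha⁻¹ for
  CK/CF/M1/M2/M3, trends −70/+85/+25/+15/+50 kg·ha⁻¹·yr⁻¹, block SD 50,
  residual SD 40) were calibrated once so that the implied structure
  matches the published claims: a declining unfertilized control,
  10-year mean ordering M1 > M2 > M3 > CF > CK, yield stability
  increasing with soil quality across treatments (which is what a
  strong positive SQI–SYI regression, R² ≈ 0.9, encodes), and M2 the
  most stable producer. The small SDs mirror the extremely large
  published F statistics (four to five digits at df 4, 25), which imply
  near-zero replicate variance in the real trial.
- **Shock**: an optional per-treatment (year, multiplier) shock on the
  deterministic mean, default M1 × 0.75 in 2019 and *disabled* unless
  requested. It emulates the abrupt single-year M1 yield dip that makes
  M2, not M1, the SYI leader despite M1's higher mean yield; enabling
  it also drags the SQI–SYI correlation down, since M1 becomes a
  high-SQI/low-SYI outlier — the same tension the real trial showed.
- **Indicator noise**: each plot's 12-vector is multivariate normal
  around its treatment mean with SD = CV·mean (default CV 3 %, again
  reflecting the tiny published replicate variance) and an exchangeable
  correlation: ρ (default 0.6) among the ten nutrient/enzyme
  indicators, −ρ between bulk density and that block, pH independent.
  Flipping the sign of the bulk-density coordinate turns the model into
  an 11-variable exchangeable matrix, so it is positive definite for
  any ρ ∈ [0, 1). Values are truncated to their physical ranges
  (BD > 0, pH ∈ (0, 14), concentrations ≥ 0); at the default CVs
  truncation is a > 5σ event and does not measurably bias means or
  correlations.
- **Determinism**: all draws derive from `SeedSequence(master_seed)`
  with fixed spawn keys per stream (yields 0, soil 1, forest 10,
  permutation null 11), so identical configs give byte-identical
  tables and two pipeline runs from one master seed produce
  byte-identical analysis artifacts (wall-times live in a separate
  `run_log.json` outside the deterministic set).

**What passing tests on synthetic data do and do not show.** The
generator reproduces the design geometry, anchored effect sizes, block
structure and a plausible correlation pattern; it does not simulate
weather, nutrient cycling, spatial autocorrelation between neighboring
plots, non-Gaussian yield shocks (other than the single configured
dip), or measurement drift across the decade. Green tests therefore
demonstrate that the *methods* are implemented correctly and behave as
the formulas dictate under the stated conditions — not that any
particular field result is recoverable from real data with different
noise anatomy.

## Numerical choices and problem sizes

- Min-max scores are clipped into [0, 1] to absorb float rounding at
  the bounds; communalities are clipped the same way.
- Ties in importance ranking break by canonical predictor order
  (stable argsort); letter columns sort by their best member's mean.
- ANOVA with zero total variance reports F = 0, p = 1 with a flag.
- Test-suite problem sizes are chosen for a laptop-class single CPU:
  the permutation-importance calibration uses 100-tree forests at
  n = 200 with 99 null permutations over 20 seeds, and the
  ANOVA-calibration check uses 2000 simulated null trials; the
  pipeline's own defaults (1000 trees) are used by the acceptance
  script. Monte-Carlo bounds in the tests (3σ bands, binomial 95%
  bounds, KS < 0.05) follow from those sizes.

## Known limitations

- One-way ANOVA only; the block factor is carried as metadata, not
  modeled. No repeated-measures analysis across years.
- No nonlinear (sigmoid/optimum) indicator scoring curves and no
  minimum-data-set indicator selection.
- The compact letter display is exact for the comparisons it is given;
  with `lsd` the family-wise error is uncontrolled by construction.
- Forest importance at n = 30 with 12 correlated predictors is
  descriptive: ranks are reproducible under the seed policy, but
  variance-explained figures at that size are strongly
  generator-dependent and should not be over-read.
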