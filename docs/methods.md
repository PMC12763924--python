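# Methods

This note documents the statistical machinery, the synthetic-data model and
the design decisions behind `mvpatrial`, in the spirit of a model-reference
page: what is computed, under which assumptions, and what the defaults mean.

## 1. Epoch processing

Input is a per-child, per-day sequence of triaxial activity counts at a
fixed epoch length (1 s by default). Processing rules:

* **Window** — epochs outside 08:30–15:30 (preschool hours) are discarded;
  the half-open convention `[start, end)` makes the 7-h window exactly
  420 min of 1-s epochs.
* **Non-wear** — a maximal run of consecutive zero counts on the *vertical*
  axis lasting ≥ 20 min (inclusive at the boundary) is non-wear; the mask is
  applied to all three axes. Any single nonzero epoch breaks a run. The
  vertical-axis choice is a convention (the rule is stated for "zero
  counts" without an axis); detecting on all-axes-zero would flag slightly
  less non-wear.
* **Classification** — cut points are published in counts per minute (cpm);
  an epoch count is scaled by `60 / epoch_len` and compared with the cpm
  thresholds, keeping all comparisons in integer arithmetic at 1-s epochs.
  Two descriptors coexist, with their printed boundary conventions
  preserved: the traditional 4-class descriptor uses inclusive upper bounds
  (SED ≤ 100, LPA 101–2295, MPA 2296–4011, VPA ≥ 4012 cpm, vertical axis),
  the 17-bin spectrum uses lower-inclusive edges (0–99, 100–999, then
  1000-cpm bins to 14000–14999, ≥ 15000). Consequently a rate of exactly
  100 cpm is sedentary in the traditional descriptor but bin 2 of the
  spectrum — a deliberate preservation of the printed conventions, not a
  bug. The triaxial descriptor applies the 17 bins to each axis
  (51 variables).
* **Validity** — a day is valid if it is a weekday (Mon–Fri; the window is
  a preschool window, so weekends never qualify) with ≥ 300 min (5 h) of
  wear; a measurement is valid with ≥ 3 valid days, averaged unweighted.
  Closure holds exactly at every stage: per axis, bin minutes sum to wear
  minutes.

## 2. Change scores and analysis populations

Change is modelled as the *residualized change*: per variable and
follow-up, the residual of the OLS regression (with intercept) of the
follow-up value on the baseline value, computed on the analysis population
after subsetting, pooled across arms. Residuals are mean-zero and
uncorrelated with baseline by construction; a zero-variance baseline falls
back to centered follow-up with a warning. Analyses are complete-case per
follow-up. Intention-to-treat keeps every child with baseline and the
requested follow-up; per-protocol keeps control children plus intervention
children from high-fidelity preschools. Note that residualized change only
removes the *expected* regression-to-the-mean component; a baseline
imbalance that persists (e.g. stable cluster effects) is attenuated by the
regression slope, not eliminated — one reason the univariate arm handles
baseline imbalance differently (below), and a reason the generator treats
arms as exchangeable (Section 5).

## 3. Multivariate pattern analysis

* **Autoscaling.** X (change scores) and y (group, 0/1) are scaled to unit
  variance. Spectrum bins span orders of magnitude in variance; without
  autoscaling the large bins would dominate the covariance criterion.
  Zero-variance columns are dropped with a warning and reported.
* **Covariate projection.** Each covariate (wear-time change first, then
  baseline total activity in cpm; order configurable) is removed from every
  column of X, from y and from the remaining covariates by a rank-one
  projection — jointly equivalent to least-squares residualization on
  [1, C]. Residuals are exactly uncorrelated with the covariates.
* **PLS1 (NIPALS).** Components maximize covariance with y with standard
  deflation. At A = rank(X) the coefficients equal the OLS solution (a test
  asserts this to 1e-8, plus an independent cross-check against
  scikit-learn's PLS implementation).
* **Monte Carlo validation.** 1000 repetitions (tests and examples use
  100–500), each holding out 50% of subjects. Out-of-sample explained
  variance for the a-component model is 1 − SS_res/SS₀, with SS₀ referenced
  to the calibration-fold mean (the 0-component model). The "validation
  threshold of 0.5" is interpreted as: component a is retained iff it beats
  the (a−1)-component model in *more than 50% of repetitions*; the selected
  order is the longest passing prefix. An alternative reading (median
  improvement > 0) is nearly equivalent for continuous improvement
  distributions. No passing component ⇒ non-predictive model, and effects
  are suppressed (configurable). The validated explained variance is the
  *median* out-of-sample explained variance at the selected order (mean vs
  median is not determinable from the source; medians are robust to the
  occasional degenerate split).
* **Target projection.** t_TP = Xb/‖b‖, p_TP = X′t_TP/(t_TP′t_TP). The
  multivariate correlation is defined as
  r_j = corr(x_j, t_TP)·corr(t_TP, y) — the association of each variable
  with the single predictive direction, attenuated by that direction's
  correlation with the outcome. This product definition satisfies the two
  properties the interpretation requires: |r_j| ≤ 1, and exact reduction to
  the bivariate Pearson correlation when X has one column. Other
  formulations exist in the chemometrics literature; for one-component
  models they coincide.
* **Effect sizes.** SMD_j = r_j/0.5 (0.5 is the SD of a balanced binary
  group coded 0/1 — the "2 SD" standardization for binary predictors), and
  min/day_j = SMD_j·SD(x_j), where SD(x_j) is the SD of the
  covariate-adjusted change score on the minutes scale. CIs are percentile
  intervals of r_j over Monte Carlo half-sample refits at the selected
  order, mapped through the same affine transforms; half-sample percentile
  intervals are slightly conservative relative to full-sample bootstrap.
  The refits reuse the full-sample covariate projection (the projection is
  rank-2 and stable; redoing it per half changes intervals negligibly).
* **Clustering.** Deliberately not modelled, matching the method's standard
  tooling; the default 99% CI level (vs 95%) compensates conservatively —
  the widening is ~32% (z 2.58 vs 1.96). For non-clustered designs set
  `ci_level=0.95`.

## 4. Linear mixed model arm

Per outcome variable, REML estimation (statsmodels `MixedLM`) of

    Y = β₀ + β₁·t7 + β₂·t18 + β₃·t7·group + β₄·t18·group + β₅·wear + u_ps + u_child + ε

with dummy-coded follow-ups, **no group main effect** (both arms share the
baseline mean, absorbing baseline imbalance into the random intercepts),
concurrent wear time as a time-varying main effect, and random intercepts
for preschool and for child nested in preschool. β₃/β₄ are the 7- and
18-month effects with Wald 95% CIs. ICC_preschool =
σ²_ps/(σ²_ps + σ²_child + σ²_ε). Negative variance estimates are truncated
at the zero boundary and flagged. SMDs standardize by the pooled (both
arms) baseline SD of the outcome — the conventional trial standardizer;
the source is silent on this denominator. On balanced noise-free panels β₃
equals the difference-in-differences of cell means (tested).

## 5. Synthetic trial generator

The generator defines the conditions every simulation-based test runs
under. Design:

* **Composition.** Per descriptor-axis block, minutes are wear time ×
  logistic-normal shares: alr coordinates (reference = largest bin) are
  Gaussian, exponentiated and normalized. Closure is exact by construction
  and the sedentary-vs-active trade-off emerges naturally.
* **Calibration.** Target means/SDs are the source trial's descriptive
  table: intervention-arm baseline SED/LPA/MPA/VPA = 284 (23) / 101 (15) /
  24.7 (5.9) / 22.8 (8.0) min/day, wear 433 (19); control-arm secular drift
  at the follow-ups is applied to both arms. alr SDs come from a
  delta-method inversion of the minute SDs (net of the wear-variance
  contribution); the *reference-bin* SD pins down an equicorrelation among
  the non-reference alr coordinates (solved, not guessed: the reference
  share moves only when the others move jointly). alr means are then
  calibrated so that E[share] hits the target shares, by a fixed-seed Monte
  Carlo iteration (4000 draws, 8 multiplicative updates) that is
  independent of the user seed — E[share] of a logistic-normal has no
  closed form. Realized large-sample means match targets to < 0.5 min/day.
* **Arm exchangeability.** Both arms share one baseline distribution,
  anchored to the intervention column of the descriptive table. The printed
  arm differences (~6 min/day SED) are treated as what randomization makes
  them: cluster-level chance. Hard-coding them as systematic differences
  (available via `arm_specific_baseline=True`) makes every replicate
  baseline-imbalanced and biases change-score estimands (Section 2).
* **Hierarchy.** Each alr coordinate's variance is split preschool : child :
  occasion = 0.08 : 0.50 : 0.42 by default. The preschool fraction is the
  target ICC; the child fraction (0.50) encodes moderate within-child
  tracking of activity across waves, a typical value for this age group.
  Wear time receives the same decomposition so that a single preschool
  fraction governs the realized ICC of bin minutes (wear variance would
  otherwise dilute it). Cluster sizes are Poisson(15); allocation is
  balanced to ±1 preschool.
* **Effects.** Intervention effects are injected post-hoc on the minutes
  scale: the named variable is shifted by exactly δ min/day and the
  complement is redistributed proportionally over the *unspecified* bins of
  the same block, preserving wear time and closure. When every bin carries
  an explicit effect, the net sum is renormalized over all bins (perturbing
  the injected values by ≈ |Σδ|·share — ~0.2 min/day for a realistic
  4-class pattern). Values pushed below zero are clipped and counted.
  Traditional-scale effects are propagated to spectrum bins via loading
  vectors proportional to the default bin means within each class's cpm
  region (approximate at class/bin boundary mismatches). Injecting via wear
  time was rejected because it would make wear group-informative and bias
  the wear-adjusted mixed model.
* **Attrition and fidelity.** Baseline is complete; follow-ups are retained
  independently with probability 0.78 (7 mo) and 0.75 (18 mo) —
  missing-completely-at-random, with an optional cluster-level dropout
  mode. Because retention is independent across waves, the fraction with
  baseline plus *any* follow-up (~95%) exceeds the source's 85%, whose
  dropout was correlated across waves; this matters only for that joint
  statistic, not for the per-wave analysis populations. Intervention
  preschools are high-fidelity with probability 0.5 (cluster-constant),
  giving per-protocol populations ~78% of ITT.
* **Spectrum profile.** The 17-bin baseline means/SDs are not published;
  the defaults are a monotone-decaying profile that sums to the 433 min/day
  wear time, implies ~753 cpm overall activity (matching the printed
  baseline value), and anchors bin 1 to the SED target. Anteroposterior and
  mediolateral axes reuse the vertical profile with independent draws —
  adequate for exercising the 51-variable pipeline, not a claim about real
  inter-axis structure.
* **Epoch simulator.** A Markov chain over
  {non-wear, SED, LPA, MPA, VPA} with exponential dwell times and per-state
  uniform integer count emissions whose cpm-equivalents land inside the
  state's cut-point range; non-wear emits exact zeros, and a forced
  zero-block option guarantees detectable non-wear runs for fixtures. It
  exercises the processing rules; it does not model realistic
  autocorrelation or spectral shape of child activity.

## 6. Problem sizes and numerical choices

Simulation-based tests and the acceptance script run at reduced sizes
chosen so each check's Monte Carlo standard error is small against its
tolerance: mixed-model recovery uses 34–40 preschools × ~15 children with
20–100 replicates (per-replicate SE of the SED effect ≈ 1.5 min/day →
SE ≤ 0.15 at 100 replicates against a ±0.5 tolerance); the multivariate
chain uses 300–1000 resampling repetitions instead of 1000 where only
distributional summaries are under test. Degenerate resampling splits
(zero outcome variance in a fold) are redrawn and counted; fewer than 100
successful CI repetitions is an error. PLS deflation stops early (with a
warning) when the residual covariance with y is numerically zero.
Optimizer: L-BFGS with a Powell fallback for REML; non-convergence raises
with diagnostics rather than returning silently.

## 7. What passing tests do and do not show

The generator reproduces the descriptive calibration targets, the
configured ICC, published retention rates and exact injected effects, so
recovery tests demonstrate that the estimation chains are unbiased under
the assumed data-generating process: Gaussian alr coordinates, MCAR
attrition, cluster-constant random effects, and effects expressed as mean
shifts. Real accelerometer data have heavier tails, wave-correlated
dropout, seasonality, and inter-axis dependence that the generator does not
emulate; passing tests therefore validate the *methods*, not the magnitude
of any real-world effect. The multivariate arm's CIs remain
cluster-unadjusted by design; its results on clustered data should be read
as a secondary, pattern-level analysis next to the mixed model.
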