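# Methods

This note documents the models, conventions, and design choices behind
`gridpi`, and what the synthetic-data tests do and do not establish.

## Trajectory scoring

Coordinates are meters in an arena-centered frame; angles are degrees,
counter-clockwise positive. A trial's return angles are measured at cone 3
between v⃗₁ (cone 2 → cone 3) and v⃗₂ (cone 3 → true or responded cone-1
location), via `atan2` of cross and dot products, range (−180°, 180°].

**Signed allocentric angular error** is wrap₁₈₀(A_true − A_est). The wrap
is the pure periodic map ((x + 180) mod 360) − 180 with range [−180°, 180°):
both ±180° inputs map to −180°, so wrap(x + 360k) = wrap(x) exactly for all
integers k. (Toolbox implementations that preserve +180° break this
periodicity at the boundary; the choice only affects exact half-turn
errors.) The **absolute angular error** is |A_true − A_est| *unwrapped* —
a 340° absolute error with a −20° signed error is intentional and preserves
the distinction between a large over-rotation and a small one.

Two estimators of A_est are available: the default *allocentric* estimator
(atan2 angle of the response vector, bounded to (−180°, 180°]) and a
*cumulative-turn* estimator integrating heading changes along the return
path, which can exceed ±180° (e.g. a participant who spins a full circle).
After wrapping, both give identical signed errors; they differ only in the
absolute error of multi-turn paths.

**Exclusions.** `no_return` (no trigger event, or a corrupt log whose
return path starts outside the arena — flagged with a warning);
`out_of_bounds` (any return-path sample beyond the arena square; the 30 cm
out-of-border *warning band* is a task/safety feature, not part of the
exclusion rule); `retracing` (return path passes within r = 0.5 m of
cone 2, configurable — a reproducible proxy for what is a manual judgment
on real data). Precedence: no_return, then out-of-bounds, then retracing.
For out-of-bounds trials the first intersection of the return path with the
arena border (in sample order) substitutes for the response direction,
giving a proxy signed error that removes the overturning bias exclusion
would otherwise introduce.

Per participant × condition, means are taken over included trials and
baseline-referenced change scores Δ = mean(condition) − mean(condition A)
are formed; a participant with no included trials in a condition yields a
missing Δ, dropped listwise from change-score regressions (the trial-level
mixed model is unaffected).

## Grid-code GLMs

Events are partitioned odd/even by index (estimation/test); the
first-half/second-half *temporal* split is reserved for temporal stability.
Task regressors are boxcars of the stated duration (sticks if durations are
zero/missing) convolved with the canonical double-gamma response (SPM
parameters, via nilearn) on a 0.1 s grid and sampled at the TR; parametric
modulators are mean-centered across the events of their set before
convolution. Nuisance regressors (e.g. motion) and an intercept enter
unconvolved. Designs are rank-checked; failures name the collinear columns
(all-equal headings, for example, zero out the centered modulators).

Each GLM for one event set additionally models the *other* set's events —
their boxcar and their own sin/cos modulators — as regressors of no
interest. Without this, overlapping hemodynamic responses from held-out
events bias the estimates; with it, noiseless recovery is exact to machine
precision, which the tests assert.

Estimation is ordinary least squares per voxel, no prewhitening —
autocorrelation modeling is out of scope, a deliberate simplification
relative to full fMRI practice that mainly inflates the variance (not the
bias) of per-voxel estimates. Multi-block runs are handled by
concatenation; block-specific intercepts can be supplied as nuisance
columns.

The ROI mean orientation is the amplitude-weighted circular mean of 6·θ_v
(weights √(β_sin² + β_cos²)), mapped back to [0°, 60°); an unweighted mean
is available (`weighted_mean=False`) since either convention is defensible.
Cross-validated magnitude is the mean over voxels of the aligned-regressor
beta on the held-out partition, reported signed — negative magnitudes are
meaningful (anti-aligned/unstable orientations) and never clipped.
Temporal stability compares per-voxel orientations between temporal halves;
with independent uniform orientations the change is uniform on [0°, 30°] in
6-fold space, so the < 15° criterion has an exact 50% chance level, used as
the null for the group t test. Constant (zero-variance) voxels are flagged
on construction and excluded from orientation statistics and tSNR.

## Cohort statistics

- **Trial-level mixed model:** fixed effects
  fh·condition·sex + apoe4·condition·sex + caide·condition + age + education
  (the full three-way risk crossing is configurable); random participant
  intercepts with condition slopes, plus trial-order intercepts as a
  variance component *within* participant — an approximation to the fully
  crossed trial-order design, which single-grouping mixed models cannot
  express. Singular or non-converged fits fall back to intercept-only
  random structure with a warning. Per-term Wald F tests use the
  fixed-effect covariance with a residual-style denominator df (no
  Satterthwaite correction); null simulations show nominal-level behavior
  at the cohort sizes tested.
- **Change-score regressions:** OLS with type-II ANOVA. Post-hoc cell
  contrasts are estimated-marginal-means style: one prediction row per
  factor cell at covariate means, pairwise differences referred to the
  studentized-range distribution (Tukey–Kramer, family = non-empty cells);
  empty cells are reported as missing and excluded from the family.
- **CAIDE rule:** the CAIDE score already incorporates age, sex and
  education, so CAIDE-univariate models must not co-adjust for them; this
  is enforced structurally (`check_caide_covariates`). The full multi-risk
  model retains age and education as covariates.
- **Elastic net:** per permutation, a random 70/30 train/test split
  (resampled if fewer than 3 test positives), within-train
  standardization, inner cross-validation selecting penalty strength and
  mixing parameter (grid {0.1, 0.5, 0.9, 1.0}) to maximize ROC AUC, then
  the held-out AUC. "Selected" means a non-zero coefficient at the chosen
  penalty. The split proportion, folds and grids are assumptions (the
  procedure they instantiate is standard), all configurable.
- **Johnson–Neyman:** the conditional slope b₁ + b₃·m is significant where
  (b₁ + b₃m)² > t²_crit · Var(b₁ + b₃m); the quadratic is solved in closed
  form and intersected with the observed moderator range. A zero
  interaction yields an empty or full interval, never a partial one.
- **OOB chi-square:** proportions of out-of-bounds trials compared between
  groups (risk strata, above/below-median CAIDE) by a 2 × 2 chi-square
  *without* Yates correction (cell counts are in the hundreds; the
  corrected statistic is needlessly conservative). The test pools trials
  and therefore assumes exchangeable trials within group: real
  between-participant propensity differences overdisperse it, which is why
  its null calibration is demonstrated on cohorts simulated without
  participant-level noise spread.

## Synthetic-data generator

The generator's role is to emulate the *statistical structure* the
analyses assume, not the phenomenology of human walking.

- **Arena/triangles:** 4 × 4 m space, return legs 3.6–4.0 m, outward legs
  1–4 m, cones ≥ 5 cm off the walls, and cone 2 at least 1.2 m clear of the
  direct cone 3 → cone 1 line — without that clearance a *correct* direct
  return can graze the retracing corridor, conflating a good response with
  an excluded strategy. Triangles are rejection-sampled, deterministic per
  seed.
- **Agent:** walks the outward legs exactly (1 m/s, 0.1 s sampling), then
  returns along a heading = true heading + von Mises error (concentration
  per return condition; defaults correspond to heading SDs of 12°/16°/20°
  for conditions A/B/C) for a length = true length × lognormal gain
  (mean 1, SD 0.12), plus optional Gaussian encoding noise on the endpoint.
  If the planned segment exits the arena the agent walks through the wall
  with probability `oob_propensity` (0.6) — recording the out-of-border
  warning 30 cm beyond — or stops 2 cm inside it. Condition effects enter
  only through the angular-noise scale by default, because the phenomena of
  interest are angular-error-dominated; the distance-noise knob exists but
  is condition-invariant. These defaults are *uncalibrated*: per-condition
  error distributions of the reference cohort are not publicly available,
  so the defaults are plausible values chosen once, yielding ≈ 25%
  out-of-bounds and ≈ 2% retracing at default noise.
- **Cohort:** prevalences FH+ 62%, APOE ε4+ 32%, female 65%; CAIDE from a
  discretized normal (mean ≈ 5.0, SD ≈ 2.2) truncated to the observed 0–11
  range; ages 43–66; education 10–24 y. Between-participant random effects:
  heading-noise SD (4°) and log distance gain (0.05). Planted effects are
  additive shifts of the heading-noise SD keyed by (term, condition, sex),
  with `caide` acting per point, centered at 5; a zero-effect cohort is an
  exact null for every risk term. 36 trials per participant, 12 per
  condition, shuffled order.
- **BOLD:** voxel orientations θ_v = true orientation + Gaussian jitter,
  optionally drifting linearly across the run; event response
  1 + a·cos(n(φ − θ_v)) convolved with the canonical HRF at TR = 2.531 s,
  plus white noise and an optional linear baseline drift. Event headings
  are stratified over 36 ten-degree bins *within each odd/even partition
  separately*: balancing only the whole run leaves anticorrelated
  directional leakage between estimation and test sets, which manifests as
  systematic negative cross-validated magnitudes at non-signal symmetries —
  the known sampling-imbalance confound. The `heading_kappa` knob restores
  unbalanced (von Mises) sampling to study exactly that confound.

**What the simulator does not model:** biomechanics and gait variability,
speed modulation, visual-environment appearance effects, deliberate search
strategies, scanner physiology (respiration/cardiac), spatial noise
correlation between voxels, and real HRF variability. Passing tests
therefore establish correctness of the *computations* and calibration of
the *statistics* under the assumed generative structure — not that the
pipeline is robust to every artifact of real VR or 7T data.

## Problem sizes and numerical choices

Validation suites use sizes chosen to make the Monte-Carlo checks sharp at
desk scale: 500 null cohorts of 32 participants for change-regression
calibration (the first 80 also fit the mixed model), 150 homogeneous
cohorts of 24 for the chi-square, 12 null cohorts of 96 for the chance-AUC
grand mean (within one finite cohort, a chance label–feature correlation
survives every train/test split, so the cross-cohort mean is the correct
chance measurement), 200 seeds for orientation recovery / specificity /
drift robustness at 12 voxels and 72 events, and 40 cohorts of 96 for
planted-effect recovery. The documented orientation-recovery reference SNR
is amplitude/noise = 1.25. Type-I rates are judged against the central 95%
binomial interval at each suite's own n.

Determinism: every stochastic routine takes a seed or Generator;
`numpy.random.SeedSequence` spawning gives stages independent,
individually re-runnable streams. Tie-breaks and degenerate inputs:
orientations are reported in [0, 360/n) with the circular mean's
−ε mod 360 → 360 edge mapped to 0; zero-length vectors raise (undefined
heading); constant outcomes yield F = 0, p = 1 rather than 0/0; zero-
variance voxels are excluded with warnings; empty Tukey cells are reported
missing. Trajectory CSVs store coordinates at full precision (scoring
re-reads them); derived tables use 9 significant digits.
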