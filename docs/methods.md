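# Methods

`soundlasso` analyses clustered sound-evaluation survey data: each
participant reports on a handful of listening situations, so
observations are nested in participants, and the analysis questions are
(i) which of many situational, sound-related and person-related
variables predict the annoyance rating, and (ii) how large factor-level
differences in annoyance are, with uncertainty that respects the
clustering. This note documents the models, the algorithms, the
defaults, and what the synthetic-data experiments do and do not show.

## The random-intercept model

All regression models are Gaussian random-intercept models

y_ij = x_ij' β + u_i + e_ij,  u_i ~ N(0, τ00),  e_ij ~ N(0, σ²),

with i indexing participants and j their listening situations. The
participant intercept u_i absorbs stable individual differences in how
annoyance scales are used; τ00/(τ00 + σ²) is the adjusted intraclass
correlation (ICC), the share of non-fixed-effect variance attributable
to between-participant differences.

**Estimation.** The criterion (ML or REML; REML is the default) is
profiled over the variance ratio θ = τ00/σ²: for fixed θ the
whitened Gram forms X'V0⁻¹X, X'V0⁻¹y, y'V0⁻¹y (V0 = I + θZZ') have
closed per-cluster expressions, β and σ² follow in closed form, and the
criterion becomes a smooth scalar function of θ maximised by a bounded
Brent search on log θ (range e⁻¹⁴…e¹², absolute tolerance 1e-10 on the
log scale). The boundary τ00 = 0 is always compared explicitly and
returned when it attains the higher criterion; with τ00 = 0 the fit is
exactly ordinary least squares. When every participant contributes a
single observation, τ00 is not identified; the fit returns the OLS
solution with τ00 = 0 and a warning flag. The implementation is checked
in the test suite against statsmodels' `MixedLM` (agreement to ~1e-6 on
coefficients and variance components) and against closed-form one-way
ANOVA estimators on balanced data.

**Satterthwaite tests.** Fixed-effect t-tests use Satterthwaite degrees
of freedom df = 2·Var(c'β̂)² / Var[Var(c'β̂)]. The gradient of
Var(c'β̂) in (τ00, σ²) and the observed information of the REML
criterion are both obtained by central finite differences of the
closed-form profiled likelihood (relative steps 1e-5, floored at
1e-10); observed rather than expected information is used because the
profiled criterion is cheap and exact to evaluate, avoiding trace
computations over n×n matrices. At the τ00 = 0 boundary the test falls
back to the OLS residual degrees of freedom n − p. The resulting df
reproduce the known patterns: ≈ n − p without clustering,
≈ n_clusters − k − 1 for cluster-constant covariates on balanced
designs, and between n_clusters and n_obs for observation-level
covariates. p-values are reported without multiplicity correction; the
analysis reports many models and leaves error-rate control to the
reader, which is stated rather than hidden.

**R².** Marginal R² = varF/(varF + τ00 + σ²) and conditional
R² = (varF + τ00)/(varF + τ00 + σ²), with varF the sample variance
(denominator n − 1) of the fixed-effect linear predictor, computed from
the REML components by default (a `method` flag switches to ML).

## Data preparation

The composite annoyance score is the mean of the reversed
pleasant-agreement item and the annoying-agreement item, both on
1–5 agreement scales, giving 1 = very pleasant, 5 = very annoying.
Items are handled internally in agreement coding (5 = strongly agree);
files coded in the opposite direction must be declared as such and
reversed on input, since published instruments disagree on direction.
Loudness ratings 1–3 are grouped as low-level and 4–5 as
mid/high-level. Ordinal median splits put values equal to the median in
the upper ("calm") class by default — with a 1–5 liveliness scale and a
median of 4 the 4s must land somewhere, and the policy is configurable
and recorded. Income per household member is the income-interval
midpoint divided by household size (midpoints are supplied via
configuration; "6 or more" persons is coded 6; missing income
propagates). Factors are treatment-coded with the most frequent level
as reference (ties break to the lexicographically first tied level, a
documented arbitrary choice), and all predictor columns including
dummies are z-standardised with denominator n − 1 so that one penalty
weight shrinks all coefficients fairly; the per-column mean/SD record
allows reporting on either scale. Rows with missing values in modelled
variables are dropped per model and counted.

## The penalized model and its solver

Variable selection minimises

(y − Xβ)' V0⁻¹ (y − Xβ) + λ·P(β),

which at θ = 0 is exactly the Lasso loss (residual sum of squares plus
λ‖β‖₁). P is, by default, the groupwise-L2 norm Σ_g ‖β_g‖₂ over model
terms — all dummies of one factor shrink together and leave the model
at the same λ — with the plain L1 sum available as an option, since the
two conventions coexist in the literature. Group weights are 1 by
default; a flag enables √(group size) scaling, which is also left off
by default because the unscaled version matches the "same amount of
shrinkage for all dummies of a factor" convention. The intercept is
never penalized, and the random-intercept variance is never penalized.

The solver alternates, to a joint fixed point (relative objective
change < 1e-8, at most 100 outer iterations):

1. **Exact blockwise coordinate descent** on the whitened quadratic
   given (τ00, σ²): singleton blocks soft-threshold in closed form;
   multi-column groups solve their subproblem exactly via the block's
   eigendecomposition and a monotone Newton iteration on the group-norm
   scalar equation (convergence tolerance 1e-14 on the stationarity
   residual; coefficient-change tolerance 1e-11 per sweep). Zeros are
   exact products of thresholding, never epsilon-truncation.
2. **ML variance components** given β: the profiled score in θ is
   root-found by safeguarded bisection on the residuals' cluster sums.

Because step 1 is exact per block and step 2 is an exact maximisation,
the objective is non-increasing and warm starts along the λ grid can
only improve the converged objective (unit-tested). The whole loop runs
on sufficient statistics (Gram matrices and per-cluster sums), so one
fit costs O(n_clusters·p²) per iteration independent of n; the inner
loops are compiled with numba. Correctness is audited by
Karush-Kuhn-Tucker checks at every grid point and, on small instances,
by a dense grid-search minimizer.

**λ_max and the grid.** With θ fixed at 0, the smallest λ that zeroes
every penalized coefficient has the closed form
max_g ‖2 X_g'(y − ŷ_unpen)‖/w_g from the stationarity conditions at
zero. When variance components co-adapt, that bound seeds a bisection
on the fitted path (relative tolerance 1e-6). The 100-point λ grid is
exponential, grid_i = λ_max·(e^{s·i/(n−1)} − 1)/(e^s − 1) with
curvature s = 4, putting resolution where coefficients move (near 0);
the curvature is a free choice documented here, since only the
qualitative shape ("higher resolution toward zero") is prescribed by
the method the package implements.

## Cross-validation, the 1-SE rule, and the percentile Lasso

K-fold cross-validation (K = 5 by default) splits **participants**, not
observations: a random permutation of clusters is dealt round-robin
into folds (cluster counts differ by at most one), so no participant
straddles training and validation. Held-out predictions use the fixed
effects only — the random intercept of an unseen participant has
expectation zero, which is the only coherent choice when validating on
new people. CV error is the mean of the K fold MSEs; its SE is their
standard deviation over √K, evaluated at the argmin λ (the standard
1-SE convention; a per-λ variant is available). The 1-SE rule picks the
largest λ whose CV error is within one SE of the minimum — the most
parsimonious model statistically indistinguishable from the best.
Because that choice is sensitive to the fold lottery, the whole CV is
repeated R = 100 times (independent fold assignments from child seeds
of the master seed) and the final λ is the 95th percentile of the R
per-cycle optima, computed by linear interpolation between order
statistics (the percentile definition is stated because conventions
differ). The λ grid is built once from the full data's λ_max, matching
a pipeline in which λ_max is determined in advance. The model is refit
at the final λ; surviving terms are then refit unpenalized with
Satterthwaite tests, R², and ICC. Non-significant survivors are
reported as such — the 1-SE rule selects on prediction error, not
p-values, and can legitimately retain them.

## Cluster bootstrap for marginal means

Estimated marginal means (EMMs) of annoyance for one or two additive
categorical factors come from an ordinary linear model on treatment
dummies; for a single factor this is exactly the per-level mean, and
with a second additive factor the fitted difference between its levels
is constant across the first factor's levels by construction.
Uncertainty comes from resampling whole participants with replacement
(n_clusters draws per resample, multiplicity preserved via replicate
IDs): percentile 2.5/97.5 bounds over B resamples. B defaults to
50,000 in the command-line interface; the coverage experiment and tests
use B = 1,000, which is where the percentile endpoints stabilise at
these sample sizes. Plain percentile intervals are used (no
bias-correction) — the method being mirrored reports plain bootstrap
intervals. A resample can lose a rare factor level entirely; affected
cells are recorded as missing, excluded from the percentile
computation, and counted in the output, a policy documented here
because no convention exists. The resample loop runs on per-cluster
Gram blocks, so 50,000 resamples cost seconds. Calibration: over 200
synthetic replicates (200 clusters, ICC 0.26) the 95% intervals cover
the true factor-level means ~94–95% of the time (pooled over levels).

## Inter-rater reliability

Krippendorff's alpha for nominal codings uses the coincidence-matrix
formulation: units with fewer than two ratings contribute nothing;
within a unit of m pairable values every ordered pair contributes
1/(m − 1); alpha = 1 − D_o/D_e with D_e computed from the pooled value
marginals. The implementation is verified to 1e-12 against an
independently coded brute-force pair enumeration. Confidence intervals
bootstrap **units** (rows) with replacement, B = 1,000 by default;
resamples on which alpha is undefined (single observed category, or no
pairable values) are excluded and counted. The conventional
interpretation bands — ≥ 0.800 reliable, 0.667–0.800 tentative — are
exposed as a labelling helper.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: 1,301
participants contributing 1–3 listening situations each with
P(1, 2, 3) = (0.28, 0.29, 0.43) — mean 2.15, hence ≈ 2,800 observations
in expectation (only totals are published; the distribution is a
documented choice) — an annoyance outcome with τ00 = 0.21 and
σ² = 0.60 (ICC ≈ 0.26) on the 1–5 scale, and a predictor roster
mirroring the survey: 9-point affect scales (valence, arousal,
control), the eight DIAMONDS situation dimensions, fade-out abilities,
binary active coping, loudness/timbre/tonality, a 3-level macro sound
category at prevalences (0.32, 0.20, 0.48), a 6-level location, and
person-level demographics and traits held constant within participant.
Default effect sizes are moderate and dominated by situational
variables, with the intercept calibrated so the expected outcome mean
is ≈ 2.84 (just below the neutral point, as observed in such surveys);
the defaults give marginal R² ≈ 0.4–0.5.

Design choices: (i) the default outcome is **continuous and
unclipped**, so parameter-recovery tests are exact in expectation;
an "item mode" instead generates the two 5-point items (pleasant
reversed, annoying) whose composite is the outcome, rounded and clipped
to 1–5, for end-to-end pipeline tests — separating estimator
correctness from measurement coarseness. Clipping policy is recorded in
the dataset metadata. (ii) Likert predictors threshold latent normals
at equal-probability cut points. (iii) Every predictor, the cluster
structure, and the noise draw from named substreams of the master seed,
so adding a predictor never perturbs the others (unit-tested).
Datasets are byte-identical across runs with equal seeds.

What passing tests show — and don't. The generator draws predictors
independently; real survey predictors are correlated (the affect and
situation scales substantially so), responses are discrete and clipped,
and missingness is structured. Recovery and coverage results under the
generator therefore certify the estimators and the selection machinery
under the stated two-level Gaussian conditions, not the field behaviour
of the survey instrument; multicollinearity robustness is exactly what
the group penalty is for, but its degree in real data is not emulated
beyond what a user configures. The rating generator's copy-noise model
(rater reports the true label with probability a, else a uniform other
label) implies pairwise agreement a² + (1 − a)²/(k − 1) — note the
degenerate corner a = 0, k = 2 where both raters always agree on the
wrong label.

## Problem sizes in the shipped experiments

The repetition counts used by the tests and the acceptance script are
the package's own desk-scale choices: selection recovery runs 25 master
seeds × (R = 20 cycles, K = 5) on 500-cluster data (the full procedure
defaults to R = 100); bootstrap coverage runs 200 replicates at
B = 1,000; the study-scale end-to-end run uses the full 1,301-cluster
generator with R = 20. All randomness derives from a single seed
through named child streams.

## Known limitations

- Only a single random intercept: no random slopes, crossed effects, or
  non-Gaussian responses.
- The Satterthwaite information is finite-differenced; for variance
  components within ~1e-8 of the boundary the test falls back to OLS
  degrees of freedom rather than attempting one-sided corrections.
- Percentile (not BCa) bootstrap intervals; with very few clusters they
  can undercover.
- EMMs are defined for one or two additive factors, matching the models
  they mirror; interactions are out of scope.
- The two-factor bootstrap shares one clustering level; designs whose
  dependence spans several factor levels need a different resampling
  scheme.
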