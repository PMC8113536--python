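# Methods

This note documents the statistical machinery in `sivcmscreen`: the model,
the estimation and selection algorithm, the preprocessing conventions, the
screening stages, the synthetic-data generators, and the numerical choices
made where the design was genuinely open.

## The single-index varying coefficient model

The response is modeled as y_i = Σ_{j=0}^p g_j(θᵀZ_i) x_ij + ε_i with
x_i0 ≡ 1, Z_i = (longitude, latitude, year), ‖θ‖₂ = 1 and θ's first
nonzero component positive (the direction is identifiable only up to sign
and scale; `normalize_direction` maps any vector to this canonical
representative, cascading to the next component when leading components
are exactly zero). Responses, predictors (except the ones column) and
index covariates are standardized before fitting, so θ is expressed on
comparable coordinate scales and the index range is stable across
datasets.

## Estimation and selection (LSSGLASSO)

Each g_j is expanded in a cubic B-spline basis with 8 interior knots at
empirical quantiles of the index values (dimension L = 12). The design has
one L-column block per predictor, x_j ∘ B(u); the fit minimizes

    (1/2n)‖y − Σ_j (x_j ∘ B)γ_j‖² + λ Σ_{j≥1} √L ‖γ_j‖₂.

**Block coordinate descent.** Each block update is solved exactly: the
block minimizer is zero iff ‖D_jᵀr/n‖ ≤ λ√L, and otherwise follows from a
monotone scalar secular equation in the eigenbasis of the block Gram
matrix, solved by safeguarded Newton with a warm-started multiplier. The
λ = 0 limit is computed directly as least squares on the expanded design.
Returned solutions satisfy the group-KKT conditions to 1e-7 (checked
against a 1e-6 certificate in the tests); solves inside the BIC path run
at 1e-5 for speed, and the solution at the chosen λ is re-polished at
1e-7 before being returned.

**Index updates.** With spline blocks fixed, one damped Gauss–Newton step
is taken on θ using the analytic basis derivative; the step is halved (up
to 10 times) until the RSS does not increase, and the result is
renormalized. Index values outside the basis boundary are clamped, so the
design never contains NaNs during line search. Basis knots are frozen
within each per-λ fit; rebuilding them mid-alternation would break the
monotone-objective guarantee.

**Initialization.** The index objective is nonconvex and the naive OLS
start (coefficients of y on Z) is unreliable — on null designs it can be
60–80° from the truth, and a misestimated index leaves intercept-function
structure in the residuals that the group LASSO then "explains" with
spurious predictors. The package therefore screens starts globally: a
coarse grid of unit directions (Fibonacci half-sphere for 3-D indices) is
scored by the intercept-only single-index profile (one spline regression
per direction), the best grid directions plus the OLS and random starts
are refined by the alternating fit on the intercept-only model, and the
two best refined candidates run a short group-LASSO pilot; the winner
seeds the full path. `n_restarts` controls the number of random starts.

**Tuning.** BIC(λ) = n·log(RSS_λ/n) + df_λ·log n with df_λ = L(|S_λ|+1),
minimized over a 50-point log-spaced path from λ_max down to λ_max·1e-3
(ties go to the larger, sparser λ). λ_max is exact only at the initial
index, and a direction update can let groups re-enter, so the sparse end
of the automatic path is extended upward (λ doubling, at most 8 times)
until the sparsest fit is genuinely empty — without this the empty model
can be absent from the path and null data acquire one spurious variable.
An explicitly supplied λ grid is used exactly as given.

Small-sample caveat: with n below roughly 8–10 observations per spline
parameter, the mechanical RSS drop from adding a 12-df block can outrun
the log(n) penalty, and coarse λ grids confound shrinkage with model
size. Per-year fits should have ~100+ rows (the `min_rows` floor of 30 is
a hard minimum, not a recommendation), and grids below ~25 points are
only suitable for smoke tests.

**Refit.** Selected functions (plus g₀) are re-estimated by local-linear
kernel regression (Epanechnikov) on the index, backfitting partial
residuals for 5 cycles or to a 1e-5 relative change, with the
rule-of-thumb bandwidth h = 1.06·sd(u)·n^(−1/5) and a 10-nearest-neighbor
floor where the window is empty. Local-linear smoothing reproduces
constants and linear functions exactly, which the tests exploit as exact
oracles.

## Preprocessing

**VIF screening.** VIF_i = 1/(1−R_i²) from regressing column i (with
intercept) on the rest; backward elimination removes the round-maximal
VIF above 5, recomputing each round, with ties broken toward the later
column (deterministic, auditable); exact collinearity reports +∞,
constant columns are flagged NaN rather than eliminated. The whole trail
is returned for audit and is tested against a from-scratch brute-force
re-implementation.

**Interpolation.** Station values are moved to survey locations by
inverse-distance weighting with power 2 within each (variable, year,
month) slice — stations never move across months; a space-time metric
would need an unstated time-scaling constant, so the within-slice spatial
reading was chosen. Distances are great-circle kilometres (haversine);
a zero-distance station returns its value exactly; an empty slice yields
a missing flag, never an exception. Interpolated values are bounded by
the contributing station values.

**Seasonal amplitudes.** Physical variables (air/water temperature,
pressure, wind, wave height, bottom temperature): mean(Jun, Jul, Aug) −
mean(Dec, Jan, Feb). Chemical/biological variables (plankton,
chlorophyll, alkalinity, nutrients, oxygen): mean(Aug, Sep, Oct) −
mean(Mar, Apr, May). December belongs to the *previous* calendar year by
default (the winter preceding the summer); the convention is a config
switch (`djf_year_convention`) because either reading is defensible. Any
missing required month flags that year as missing.

**Lag alignment.** A response at (location, year t) is paired with
amplitudes at (location, t − lag); the default species lag map is 10
years for Pacific halibut and 5 for all other species, reflecting female
maturity ages. Rows with any missing lagged amplitude are dropped
listwise and counted.

## Per-year selection

Selection runs once per survey year and once pooled ("allyrs"); each cell
of the resulting variable × year matrix is 1, 0 or NA (year absent or
below `min_rows`). Within a single-year fit the year coordinate is
constant and unidentifiable, so the index reduces to a unit 2-vector over
(longitude, latitude) under the same sign convention. The pooled run uses
exactly the union of the per-year rows (asserted). Matrices serialize to
TSV with legend {1, 0, NA} and round-trip losslessly.

## Climate screening

Per-year amplitudes of each climate index are mean(JJA) − mean(DJF). For
every (variable, index) pair within a species-response, a logistic
regression of the binary selection indicator on the lagged amplitude is
compared with an intercept-only model by likelihood ratio (χ²₁), for
screening years 1985–2013. Constant series are flagged untestable and
(quasi-)separated fits are flagged, both with missing p-values, rather
than producing spurious numbers. The binary fit is a standard logit-link
binomial GLM (IRLS, via statsmodels). p-values are Benjamini–Hochberg
adjusted; the family is all variable × index tests within one
species-response (pooling the three indices — the alternative per-index
family is a config switch). The step-up adjustment is implemented
directly and verified against statsmodels' implementation; note that BH
adjustment is not idempotent, so re-adjusting adjusted values is not a
supported operation.

## Additive climate models

Each yearly response is fit as E(y) = f₀ + f₁(PDO_lagged) + f₂(MEI) +
f₃(NPGO) with penalized cubic B-spline smooths: uniform extended knots
(the Eilers–Marx P-spline construction, whose second-difference penalty
null space contains exactly the linear functions of the covariate),
basis dimension 10 per smooth, sum-to-zero identifiability via a QR
reparametrization. Only PDO carries the lag, following the model
equation. Smoothing parameters minimize GCV with the usual γ = 1.4 df
inflation (guarding against small-sample undersmoothing) by
coordinate-wise grid search; GCV's numerator is floored at numerical
zero so near-interpolating fits tie on RSS and resolve toward the
smoother candidate. Per-smooth p-values are Wald-type statistics on the
smooth's coefficients under the Bayesian coefficient covariance with the
smooth's effective df, referred to an F distribution with residual df
from the influence trace — the combination that proved calibrated at
n = 29 (null rejection ≈ 0.05–0.08, null deviance explained ≈ 0.2).
Deviance explained is 1 − RSS/TSS.

## Synthetic data

The generators define the study conditions for every test: SIVCM draws
with longitude ~ U(−170, −130), latitude ~ U(50, 62), survey years
1984–2013 (standardized before the index is formed, matching the
estimator), standard-normal predictors (optionally equicorrelated),
Gaussian noise, and default truth g₀ = sin(πu), one linear and one
quadratic coefficient function among p = 10 candidates (the 25-predictor
field setup is available as the `paper25` preset; it keeps the
literature's unresolved inconsistency about salinity, which appears among
amplitude variables but not among obtained variables). `noise_sd_for_snr`
calibrates the noise to a target signal-to-noise ratio; the consistency
simulations run at SNR ≈ 5 with n = 400. Monthly station and
climate-index series carry configured seasonal structure whose amplitudes
round-trip exactly through the preprocessing at zero noise; binary
selection series follow Bernoulli(expit(β₀ + β_k·amplitude)). All
generators are deterministic under a fixed seed and retain their ground
truth. What they deliberately do not emulate: realistic spatial
covariance of the Gulf of Alaska, buoy gap patterns, or non-Gaussian
catch distributions — passing tests demonstrate correctness of the
machinery under known truth, not field realism.

## Problem sizes

The test suite and the acceptance script run simulations sized to finish
in minutes on one CPU: 25 replicates at n = 400 for the selection
consistency checks (10 in the acceptance script), n = 500 for index
recovery, 1000 null replicates for the LRT calibration, 200 (tests) or
100 (script) for the additive-model null, and an 800-row, 8-year pipeline
for the determinism check. These sizes were chosen so each property is
measured with adequate precision (binomial standard errors of a few
percent) while keeping the whole suite fast.

## Known limitations

- No inference (standard errors or bands) for θ̂ or ĝ_j.
- The group-LASSO+ridge and group-SCAD+ridge penalty variants are not
  implemented.
- BIC on penalized fits is conservative-to-liberal depending on n and
  grid resolution (see the small-sample caveat above).
- The additive-model p-values are Wald-type approximations; their
  calibration was verified at the n ≈ 29 yearly scale the pipeline uses,
  not asymptotically.
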