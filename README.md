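# sivcmscreen

Variable selection for **single-index varying coefficient models (SIVCMs)**
of spatiotemporal survey data, with the surrounding pipeline used in
fisheries-environment studies: seasonal-amplitude covariate engineering
from monthly station series, collinearity screening, per-year selection
matrices, and FDR-controlled screening of selection patterns against
North Pacific climate indices (PDO, MEI, NPGO).

## The model

For a survey response y_i (e.g., CPUE or mean weight of a groundfish
species) observed at longitude/latitude/year Z_i = (z1, z2, z3) with
environmental predictors X_i = (1, x1, ..., xp):

    y_i = Σ_j g_j(θᵀ Z_i) · x_ij + ε_i,        ‖θ‖₂ = 1, θ₁ > 0

Each regression coefficient is a smooth function g_j(·) of the scalar
spatiotemporal index θᵀZ, so the strength of every environmental effect
can drift across space and time. Estimation (LSSGLASSO) expands each g_j
in a cubic B-spline basis (8 interior knots at index quantiles, basis
dimension 12) and alternates

1. a **group-LASSO** fit of the spline coefficient blocks — penalty
   λ Σ_{j≥1} √L ‖γ_j‖₂ zeroes whole coefficient functions, performing
   variable selection (block coordinate descent with exact block
   minimization; the intercept function g₀ is never penalized);
2. a damped **Gauss–Newton step** on the index direction θ, renormalized
   to the unit-norm, positive-first-component representative.

λ is tuned by a BIC-type criterion, n·log(RSS/n) + L(|S|+1)·log n, over a
50-point path whose sparse end always contains the empty model. Selected
functions are re-estimated by Epanechnikov local-linear regression with
backfitting.

Around the estimator, the package implements the full study pipeline:

- `preprocess` — VIF backward elimination (threshold 5), inverse-distance
  weighted interpolation of monthly station data to survey locations
  (haversine distances), summer−winter / fall−spring seasonal amplitudes,
  and maturity-lag alignment (5 years; 10 for Pacific halibut);
- `selection` — per-year and pooled ("allyrs") selection matrices;
- `climate` — logistic likelihood-ratio screening of binary selection
  series on lagged climate-index amplitudes with Benjamini–Hochberg FDR,
  and a three-smooth penalized-spline additive model per response;
- `synthetic` — generators for every input with known ground truth;
- `io` / `cli` — delimited-text schemas, YAML config, manifests, and the
  `sivcm-screen simulate|select|associate|run` command.

## Worked example

`examples/01_fit_sivcm.py` draws 400 synthetic survey observations whose
response depends on 10 candidate predictors — only x1 (linear coefficient
function) and x2 (quadratic) are real — at a signal-to-noise ratio of
about 5, then runs the full fit:

```
true index direction : [ 0.8729 -0.4364  0.2182]
estimated direction  : [ 0.8697 -0.4442  0.215 ]
angle error          : 0.52 degrees
true nonzero set     : [1, 2]
selected set         : [1, 2]
lambda* (BIC)        : 0.0094 over a 51-point path
```

The estimated index direction is half a degree from the truth, and the
group LASSO recovered exactly the two truly active coefficient functions.
The other scripts in `examples/` walk through amplitude preprocessing,
the per-year selection matrix, climate screening, and the end-to-end
pipeline; each prints a short interpretation of its output.

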