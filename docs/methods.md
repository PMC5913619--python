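# Methods

## Structural model

All quantities derive from one data-generating process per individual:

    y = β₁ E_T + β₂ C_T + γ U + ε

* `(U, E_T, C_T)` — trivariate standard normal with correlations
  `ρ_UE`, `ρ_UC` and the induced `ρ_EC = ρ_UE ρ_UC`. Normality is a
  modelling choice: the asymptotic bias expression only depends on
  second moments, and a joint normal is the minimal family consistent
  with a correlation-only parameterisation. The confounder-only
  correlation channel means the implied 3×3 correlation matrix is
  positive definite for any `ρ_UE, ρ_UC ∈ (−1, 1)`; this is validated
  at construction anyway.
* `ε` — normal with mean 0 and SD `sigma_eps` (default 1). The source
  material never states this variance; it cancels from every bias
  expression and affects only Monte Carlo noise, so unit variance is
  assumed and exposed as a parameter.
* True-score variances are fixed at 1, matching the unit diagonal of
  `Q_XX`. ICC conversions default to `sigma2_true = 1` but accept other
  values.

The analyst's (misspecified) regression is `y ~ 1 + E_O + C_O`: the
confounder is omitted and the regressors are the error-laden observed
versions. An intercept is always included even though the structural
equations omit one — dichotomised regressors have mean 0.2, not 0, and
without the intercept even the no-error, no-confounding design would be
misspecified.

## Continuous design: closed form

The bias of OLS is

    E[β̂ − β] = (Q_XX + Σ_v)⁻¹ Q_XU γ − (Q_XX + Σ_v)⁻¹ Σ_v β

evaluated by solving the 2×2 linear system rather than forming the
inverse (stable as `|ρ_EC| → 1`). Degenerate special cases reduce to
textbook results and are enforced exactly in tests:

* `Σ_v = 0`, `ρ_UE = ρ_UC`: the contrast `β̂₁ − β̂₂` is unbiased for
  any `γ` and `β` (the rationale for calibration — valid only without
  measurement error);
* `γ = 0`, `ρ = 0`, error in the exposure only: classical regression
  dilution, `E[β̂₁] = β₁ / (1 + σ²_vE)`;
* `σ²_vE → ∞`: the estimate collapses to zero.

Bias curves are tabulated over a default γ grid of 51 evenly spaced
points on [0, 0.5] (the range the published curves cover) and exported
as CSV; plots are optional and never an acceptance surface.

## Binary design: simulation

Per replicate: draw latents; dichotomise `E_T` and `C_T` at the
*empirical* `quantile_cut` quantile (default 0.8, strict inequality —
ties have probability zero with continuous latents); generate `y` from
the **true binary** values; then flip each recorded class independently
with probability `p` (Bernoulli flips, identical rate in both classes).
Misclassification never touches `y` — error lives purely in what the
analyst observes. Two choices the source material leaves open are
resolved as follows and matter only at the third decimal of
finite-replicate noise: Bernoulli(`p`) flips rather than flipping an
exact count (independence gives the clean `1 − 2p` covariance
attenuation used as a test oracle), and the empirical rather than the
theoretical normal quantile for the cut.

Default simulation scale: `n = 10,000` per replicate. The published
tables state neither `n` nor the replicate count; 10,000 replicates
give an MC SE of ≈ 0.0003 per cell (third-decimal reproduction), and
the scaled-down 2,000 replicates used in the test suite give ≈ 0.0006
while keeping the suite minutes-scale.

## Randomness

Every replicate's streams derive from
`SeedSequence(master_seed, spawn_key=(cell_index, rep))`, spawned into
four independent sub-streams (latents, exposure error channel, control
error channel, outcome noise). Consequences: results are bit-for-bit
reproducible from (config, seed); cells of a grid can run in any order
or in parallel; and toggling one error channel leaves every other draw
unchanged (exploited by tests that compare corrupted and clean versions
of the same dataset).

## Estimation and degenerate replicates

OLS inside the Monte Carlo loop uses `numpy.linalg.lstsq` on the raw
design matrix (tens of thousands of small fits; statsmodels agrees to
1e-10 in the cross-check tests). A rank-deficient design — e.g. a
binary regressor falling entirely into one class — raises rather than
returning a minimum-norm solution; the replicate is dropped and
counted. At the default `n` this is vanishingly rare (probability
≈ 0.8^10000 per channel).

## A note on the reference table values

The simulated tables reproduce the published 3×3 misclassification
grids to within about ±0.011. The residual discrepancy is systematic,
not Monte Carlo noise: the reference values in the no-control-error
cells (e.g. 0.140 where this package's population value is 0.1293, and
the 0.157 control-coefficient value that is constant down a column)
coincide exactly with what *separate univariate* regressions of the
outcome on each observed regressor would give. The joint two-regressor
model partials part of the confounded signal out of each coefficient
whenever the other regressor still carries information (anything below
50% misclassification), which is why the two approaches agree exactly
in the cells where the other regressor is pure noise (±0.140, −0.200
cells) and differ by up to 0.011 elsewhere. This package implements the
joint regression throughout, since that is the stated estimating
equation and the design whose calibration logic is under study; the
exact population values used to establish this are computed in the test
suite from bivariate-normal orthant probabilities, independently of the
simulation code.

## What a green test does and does not establish

The generator emulates exactly the stated world: jointly normal
latents, non-differential error, a single confounder, no direct
exposure-control dependence, no effect of the observed covariates on
the error process. Green tests establish that the closed form, the
simulation and independent oracles agree *within that world*. They say
nothing about differential (outcome-dependent) misclassification,
correlated error between exposure and control, multiple confounders,
non-normal latents, or assortative-mating-style direct E–C correlation
— all explicitly out of scope.

## Numerical choices

* Linear systems solved, never inverted; `Q_XX + Σ_v` is symmetric
  positive definite for all valid inputs.
* Monte Carlo SE = across-replicate SD (ddof 1) / √reps; a single
  replicate reports NaN SEs.
* Validation z-scores are (analytic − simulated) / MC SE with a pass
  threshold of |z| < 3 per component.
* Parameter validation raises at construction (`ValidationError`), so
  downstream code never re-checks.
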