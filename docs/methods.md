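# Methods

`ozoneimpact` implements a four-stage framework for estimating the
mortality burden of climate-driven changes in summer ground-level ozone,
exercised end-to-end on synthetic data with recorded ground truth. The
stages are (1) a Bayesian space-time model linking daily ozone to
weather, (2) regression calibration of climate-model weather output,
(3) multi-community time-series mortality models with hierarchical
pooling, and (4) an attributable-deaths calculation with delta-method
uncertainty.

## Exposure metrics

Daily exposure is the maximum daily 8-hour average (MDA8): the maximum
over the 17 eight-hour running means that fit fully inside a calendar
day (start hours 0–16). A window is valid only if at least 6 of its 8
hourly values are present (75% completeness, `ceil(0.75 × 8)`); a valid
window's mean uses the available hours only, and a day with no valid
window is missing. Cross-midnight windows are deliberately excluded;
no additional whole-day completeness rule is applied before taking the
maximum. The regulatory design value is the 3-year mean of each year's
fourth-highest daily MDA8, compared against the 75 ppb attainment
threshold.

Coordinates are projected to planar kilometres with an equirectangular
projection about the centroid latitude (`y = 111.32·lat`,
`x = 111.32·lon·cos(lat₀)`); at the regional scale of interest the
error relative to geodesic distance is negligible, and the projection
keeps all distances exactly reproducible. Monitors are linked to the
nearest weather station by projected Euclidean distance, ties broken by
smallest station id so the linkage is order-invariant.

## Space-time ozone model

MDA8 ozone at monitor *s* on day *t* follows

    Y(s,t) = X(s,t)·β_r + e(s,t),

with X = (1, temperature °C, GHI W/m², cloud cover %) and one
coefficient vector per state (all states share the residual covariance
and are estimated jointly). The response is untransformed. The residual
field is a mean-zero Gaussian process with separable exponential
covariance

    Cov[e(s₁,t₁), e(s₂,t₂)] = σ² · exp(−‖s₁−s₂‖/ρ_s) · exp(−|t₁−t₂|/ρ_t),

distance in km, time in days. The effective range (separation at which
correlation falls to 0.05) is 3ρ by the usual convention, since
exp(−3) ≈ 0.0498.

Priors: ρ_s ~ Uniform(10, 350) km and ρ_t ~ Uniform(0, 5) days (chosen
through their effective ranges, 30–1050 km and 0–15 days);
σ² ~ InverseGamma(0.01, 0.01); β ~ N(0, 10⁸·I) — proper but flat.
Sampling is Gibbs for β (conjugate normal) and σ² (conjugate
inverse-gamma) and a joint random-walk Metropolis step on
(log ρ_s, log ρ_t) with reflection at the prior bounds and the log-scale
Jacobian in the acceptance ratio. Step sizes adapt in blocks of 25
iterations during burn-in toward a 20–45% acceptance rate and are then
frozen, preserving detailed balance for the retained draws. The default
run keeps 3000 draws after 1000 burn-in, no thinning. A prior-only mode
(`sample_prior_only=True`) switches the likelihood off; it reproduces
the uniform prior moments and is used to validate the sampler.

For complete station-by-day panels every likelihood evaluation uses the
Kronecker factorisation R = R_s ⊗ R_t via eigendecompositions of the
two factors, costing O(n_s³ + n_t³) instead of O((n_s·n_t)³); the dense
path over observed entries handles incomplete panels (missing responses
are dropped, not imputed). Cholesky/eigendecomposition failures retry
once with a 1e-8 diagonal jitter and otherwise raise. ρ_t proposals are
floored at 10⁻³ days on the log scale; the prior mass below is
negligible and the correlation matrix is numerically the identity
there.

Prediction draws, for each retained parameter draw, either the
conditional (kriging) Gaussian given the observed panel — used for the
reference period, where it reproduces the observed residual field and
hence the observed community means — or the unconditional GP around
X*β for future periods, carrying the reference-period covariance
forward unchanged. Conditioning exploits the same Kronecker structure:
with new stations on the panel's day grid the conditional covariance is
(R_s,new − A·R_s,cross) ⊗ R_t. Hold-out validation removes whole
stations (keeping at least one per state), refits, and reports RMSE and
95%-interval coverage at the held-out station-days.

## Climate-model calibration

For each county and weather variable, observed reference-period weather
is regressed (OLS) on date-matched climate-model output; the fitted
value at a future model output is the calibrated projection. This is
classical regression calibration: the model output is an error-prone
proxy and the observed series the validation data. Zero-variance or
degenerate fits fall back to slope 0 / intercept = observed mean; an
uninformative variable collapses to the reference mean through its
near-zero slope without any explicit threshold. Cloud cover is
truncated at zero after calibration. Gridded output is treated as
point values at cell centres; a county's series is the unweighted mean
over centres inside its circle, or the nearest centre if none fall
inside. Calibration uncertainty is not propagated downstream.

A structural consequence worth noting: a mean shift Δ in the true
future weather reaches the calibrated projection attenuated by the
calibration slope times the distortion slope — in the synthetic setup
exactly r² of the observed-vs-model fit. With the low-agreement regime
(r² ≈ 0.25 for temperature) most of an injected climate signal is
absorbed into the reference mean. The signal-recovery experiment
therefore uses a faithful (identity) climate model and a paired future
weather realisation (same generator seed as the reference period plus
the warming shift), so the known injection is identifiable free of
attenuation and of between-realisation summer-mean weather noise
(~0.5 ppb in ozone units at desk scale); both periods are then
predicted unconditionally for symmetry. The low-agreement regime is
retained everywhere else.

## Health models and pooling

For each community, daily death counts stacked over three age strata
(<65, 65–74, ≥75) follow a quasi-Poisson log-linear model: ozone at a
single lag (0, 1 or 2) or all three lags jointly (unconstrained
distributed lag), plus day-of-week indicators, age-stratum intercepts,
age-by-trend interactions, and natural cubic splines of the long-term
trend (3 df per summer — a pro-rata reduction of the conventional
7 df/year to summer-only series), same-day and previous-three-day mean
temperature (6 df each) and dew point (3 df each). All dfs are
configurable; trend df is the usual sensitivity dial. Summers are
disjoint blocks: lags and running means never cross seasons, so the
first three days of each summer drop from every design (the
previous-three-day means require them even for lag-0 models).

The spline basis is the truncated-power natural cubic construction
(linear tail constraint beyond boundary knots; interior knots at
equally spaced quantiles), evaluated on an input affinely rescaled to
[0, 1] so cubic terms stay well conditioned for day-index inputs.
Fitting is IRLS via statsmodels GLM on a column-rescaled design (an
exact reparameterisation; coefficients and covariances are transformed
back), with dispersion estimated by Pearson χ²/df and coefficient
variances scaled by it. Convergence is judged on the relative deviance
change (10⁻⁹), since an absolute criterion is unreachable at double
precision for deviances in the thousands. Aliased columns are dropped
with a warning; an aliased ozone column is an error. Single-lag
estimates come from separate single-lag models; the cumulative
distributed-lag effect is the coefficient sum with variance summing the
full 3×3 covariance block. Effects are stored per ppb and reported as
percent per 10 ppb, 100·(exp(10β)−1).

Community estimates β̂_c with variances ν̂_c are pooled under the
two-level normal model β̂_c ~ N(β_c, ν̂_c), β_c ~ N(μ, τ²), with a flat
prior on μ and uniform prior on τ. Instead of rejection sampling, the
τ-marginal posterior is integrated on a deterministic linear grid in τ
(2001 points from 0 to √(20·max ν̂_c), trapezoid rule); μ | τ is normal
with inverse-variance weights 1/(ν̂_c + τ²), so posterior moments,
shrunken community effects and shrinkage factors ν̂_c/(ν̂_c+τ²) are
mixture averages over the grid. The grid posterior matches a 10×
denser grid to 10⁻⁴ relative and reduces exactly to the fixed-effect
inverse-variance mean at τ² = 0. With a uniform-on-τ prior and few
communities the τ² posterior mean remains of order the sampling
variances even when the estimates coincide; it collapses toward zero
only as the number of communities grows.

## Attributable deaths

With pooled coefficient β (log rate per ppb), projected ozone change
Δx (ppb), reference-year baseline deaths N and a future horizon of
`years` seasons,

    M = {exp(β·Δx) − 1} · N · years,
    Var(M) = (N·years·exp(β·Δx))² · (Δx²·Var(β) + β²·Var(Δx)),

assuming β and Δx independent; the 95% CI is M ± 1.96·√Var(M) and is
symmetric about M by construction. Δx and Var(Δx) come from
posterior-predictive draws of community-mean ozone, paired by parameter
draw between the reference and future periods (unpaired sets fall back
to summing variances). Baseline mortality and population are held at
reference-year values; `years` defaults to 10, reading the reported
totals as decade aggregates, and per-year values are reported
alongside.

## Synthetic data generator

The generator emulates the study conditions: monitors uniform in a
regional bounding box with state labels from longitude bands; disjoint
circular communities centred on a max-min-separated station subset
(population 768,000 each, the study's 14.6M over 19 communities);
weather as a centred seasonal sinusoid plus a spatially smooth Gaussian
field (exponential correlation, 300 km range) with AR(1) day-to-day
innovation (φ = 0.6), means 24.2 °C / 240 W·m⁻² / 4.42% cloud; ozone
from the linear model plus the separable GP sampled by Kronecker
factorisation at σ² = 110.25 ppb², ρ_s = 179 km, ρ_t = 1.83 days, with
base coefficients placing mean ozone near 53.3 ppb; climate-model
output as an affine distortion plus noise per variable, noise sized so
county-level (grid-aggregated) observed-vs-model r² lands near
0.25 / 0.03 / 0.01 for temperature / GHI / cloud; and mortality as
Poisson counts with per-lag log relative risks (0.00011, 0.00023,
0.00011 per ppb), baseline 26.9 deaths per 10,000 per summer, age
shares 0.30/0.25/0.45, mild day-of-week, seasonal and weather terms,
and dew point derived as temperature minus a noisy 5 °C offset. One
global seed fans out to per-stage seeds by fixed offsets; every
generator is bit-reproducible under a fixed seed.

What the generator does not emulate: real monitor clustering around
cities (locations are uniform), instrument error in ozone
measurements, non-stationary or anisotropic residual structure,
emission-driven ozone trends, population change, and mortality
displacement. Passing recovery tests therefore demonstrate internal
consistency of the estimation machinery under the model's own
assumptions, not robustness to the ways real data deviate from them.

Desk-scale defaults keep runs in minutes on one CPU: 15 stations ×
one summer for the ozone model, 3 communities × 14 summers for the
health models, 100 posterior-predictive draws, and 3 simulated future
summers standing in for the 10-season horizon (the `years` multiplier
still reports decade totals). The signal-recovery experiment uses 19
communities and 40 stations: with 3 communities the pooled risk's
sampling error exceeds the true effect, so the sign of the resulting
death estimate would be uninformative — a power consideration, decided
by design.

## Known limitations

- Spatial-range estimation from 15 uniform-random monitors is
  inherently volatile: posterior means of ρ_s are unbiased across
  replicates but their sampling distribution is left-skewed, so
  fixed-truth frequentist coverage of the 95% intervals runs a few
  points below nominal at desk scale even though the sampler itself is
  calibrated (verified by simulation with prior-drawn truths). The
  original network of 111 clustered monitors does not have this
  problem.
- The reference period is a single summer, so its realised weather and
  residual field enter Δx; at desk scale this contributes more
  variability than the reported posterior spread of Δx reflects.
- Calibration uncertainty is not propagated into the impact CI, and the
  ozone model has no observational measurement-error component.
- The pooled-risk prior on τ is a package choice (uniform on τ); with
  few communities the heterogeneity posterior is prior-sensitive.
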