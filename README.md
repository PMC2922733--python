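# ozoneimpact

Quantifying the mortality impact of climate-driven changes in summer
ground-level ozone.

Ground-level ozone forms from precursor emissions under heat and
sunlight, so a warming climate can raise future ozone levels even with
emissions held fixed — and short-term ozone exposure is an established
mortality risk. This package implements, as a tested pipeline over
synthetic data with known truth, a statistical framework that chains
four pieces:

1. **Space-time ozone model** — daily maximum 8-hour average (MDA8)
   ozone at monitor *s* on day *t* is `Y(s,t) = X(s,t)·β_r + e(s,t)`,
   with state-specific coefficients on temperature, solar radiation
   (GHI) and cloud cover, and a mean-zero Gaussian-process residual
   with separable exponential covariance
   `σ²·exp(−‖s₁−s₂‖/ρ_s)·exp(−|t₁−t₂|/ρ_t)`. Fitted by MCMC (conjugate
   Gibbs for β and σ², Metropolis for the decay scales, Kronecker
   factorisation of the space-time correlation).
2. **Regression calibration** — per-county, per-variable OLS of
   observed weather on gridded climate-model output; the fitted value
   is the calibrated future weather. Uninformative variables collapse
   to the reference mean through a near-zero slope.
3. **Health models and pooling** — per community, quasi-Poisson
   regression of daily deaths (three age strata) on lagged ozone with
   natural-spline control for trend, temperature and dew point; lags
   0/1/2 and an unconstrained distributed lag. Community estimates
   β̂_c ~ N(β_c, ν̂_c), β_c ~ N(μ, τ²) are pooled by deterministic
   integration over the heterogeneity parameter.
4. **Attributable deaths** — `M = {exp(β·Δx) − 1}·N·years` with a
   delta-method CI treating β and the projected ozone change Δx as
   independent.

A seeded synthetic-data module generates every input the pipeline
consumes (monitor network, weather fields, ozone, biased gridded
"climate model" output, community mortality) with the ground truth
recorded, so every stage is testable by parameter recovery.

## Worked example

```python
import ozoneimpact as oi

# residual correlation at the fitted decay scales
p = oi.STCovarianceParams(sigma2=110.25, rho_s=179.0, rho_t=1.83)
print(round(oi.residual_correlation(p, 0, 1), 2))     # 0.58  (1 day apart)
print(round(oi.residual_correlation(p, 100, 0), 2))   # 0.57  (100 km apart)
print(oi.effective_range(350.0))                      # 1050.0 km

# attributable deaths from a pooled risk of 0.26% per 10 ppb, a
# 0.43 ppb ozone increase, 39,514 baseline deaths, a 10-season horizon
imp = oi.attributable_deaths(beta=0.00026, beta_var=0.0,
                             dx=0.43, dx_var=0.0, N=39514, years=10)
print(round(imp.M, 1))                                # 44.2 deaths
print(round(imp.pct_rate_increase, 2))                # 0.01 (% rate increase)

# full synthetic pipeline: simulate -> fit -> calibrate -> project ->
# health models -> pool -> impact
report = oi.run_pipeline(oi.PipelineConfig(seed=3))
ex = report["exposure_change"]
print(round(ex["reference_predicted_mean_ppb"], 2))   # 56.49
print(round(ex["reference_observed_mean_ppb"], 2))    # 56.49
print(round(report["impact"]["dl02"]["deaths"], 1))   # 3.5
```

The first block evaluates the separable residual correlation: 0.58
between consecutive days at the same site and 0.57 at 100 km on the
same day, with the effective range (correlation 0.05) at three times
the decay scale. The deaths calculation turns a pooled log-relative
risk and an ozone increase into excess deaths over a decade of summers
— a 0.01% rate increase. The pipeline run fits everything on synthetic
data: the predicted reference-period community ozone mean matches the
directly observed mean (kriging conditions on the observed field), and
the distributed-lag attributable-deaths estimate is small and positive
under the default 0.5 °C injected warming with a low-agreement climate
model.

## Analysis scripts

`analysis/01_simulate.py` … `analysis/06_assess_impact.py` run the same
pipeline as separate narrative steps, exchanging CSV tables under
`results/`: simulate inputs, fit the ozone model (with hold-out
validation), calibrate climate output, fit the health models, pool the
risks, and assess the impact. Each prints what it found; run them in
order with a shared `--seed`.

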