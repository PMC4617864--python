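# jellybloom

Spatio-temporal modelling of coastal jellyfish outbreak drivers: a
latent-Gaussian Poisson model on an SPDE mesh, the environmental bootstrap
for separating deterministic from stochastic forcing, and extreme-value
return times of outbreaks.

## The problem

Mass strandings of *Pelagia noctiluca* along a coastline are recorded as
site-days with at least one stranded jellyfish per m²; the modelled response
is the number of such outbreak days per site and month.  Two questions
drive the analysis: (1) which environmental covariates (SST, primary
production, chlorophyll-a, geostrophic currents, distance to the nearest
submarine canyon, month, year) predict outbreaks, and (2) whether outbreaks
are driven by the deterministic seasonal component of the environment or by
its stochastic anomalies.  The package implements the full chain on
synthetic data with known parameters, so every stage is testable end to end.

## The model

Counts follow a Poisson log-linear model with a spatio-temporal latent
field:

    y_it ~ Poisson(λ_it),   log λ_it = z_itᵀ β + Σ_j B_ij ζ_t(j) [+ ε_it]

where ζ_t is a Gaussian Markov random field on the vertices of a Delaunay
mesh with Matérn (ν = 1) spatial structure — represented through the SPDE
finite-element precision Q_s = (κ⁴C + 2κ²G + GC⁻¹G)/(4πκ²σ_w²), range
ρ = √8/κ — evolving as an AR(1): ζ_t = a ζ_{t−1} + ω_t, ω_t ~ N(0, Q_s⁻¹).
B maps sites to the three vertices of their containing triangle.  Inference
is an empirical-Bayes Laplace approximation (Gaussian approximation of the
latent posterior, derivative-free maximization of the approximate marginal
likelihood over κ, σ_w², a, σ_t², then a Gaussian approximation on internal
scales for hyperparameter intervals).

The **environmental bootstrap** decomposes each daily series into a 15-day
sliding-window climatology (mean and SD pooled across years) and
standardized residuals, then permutes residual blocks — sized by the
longest decorrelation time among variables, with one joint permutation per
replicate across all variables and sites — and reconstructs hypothetical
histories.  Predictions from the fitted model across replicates quantify
how much variability the randomized component drives; the mirror variant
randomizes the climatology instead.  Per-month maxima over sites feed a
GEV fit, z_T = μ + (σ/ξ)[(−log(1−1/T))^(−ξ) − 1], giving return times of
extreme outbreaks; per-site SDs under the two modes are compared with the
Wilcoxon signed-rank test.

## Worked example

The numbered drivers under `analysis/` run the whole study at desk scale
(60 sites, 500 bootstrap iterations; intermediates under `scratch/`,
summary tables under `results/`):

```sh
python analysis/01_simulate_study.py
python analysis/02_fit_outbreak_model.py
python analysis/03_environmental_bootstrap.py
python analysis/04_extreme_value_analysis.py
python analysis/05_forcing_comparison.py
```

Output of `01` (the simulated design):

```
sites: 60, env rows: 64260
monthly count rows: 1200 (20 per site)
mean outbreak days/month: 0.12, max: 3
```

Each site contributes 20 monthly records (4 years × May–September).
`02` prints the posterior table (means, SDs, 95% credible intervals for β
and the hyperparameters σ_t², σ_w², ρ, a), VIF per covariate, and held-out
validation:

```
validation: RMSE 0.340, correlation 0.139, coverage 0.992 (n=360)
```

Coverage near 0.95–1.0 means the predictive intervals are honest; the low
correlation reflects how rare outbreaks are at these rates.  `04` fits the
GEV to per-replicate monthly maxima:

```
month 5: mu=1.94 sigma=0.58 xi=-0.13 | return levels 2y: 2.15, 10y: 3.07, 100y: 3.94, 1000y: 4.56
```

i.e. a monthly maximum of ~2 outbreak days recurs every other year, and
even millennial extremes stay below 5 — return curves flatten because the
fitted shape is negative.  `05` runs the paired forcing contrast:

```
W = 0, p = 8.14e-198 (1200 pairs, 0 zero dropped)
median SD stochastic 0.0092 vs deterministic 0.0031 → stochastic > deterministic
```

Under the default synthetic conditions the anomaly component happens to
carry more of the prediction variance; the direction is a property of the
generating parameters, and the test suite verifies that a system with a
planted dominant deterministic driver yields the opposite, correct
direction.  A single `jellybloom run-all --out DIR --seed N` CLI runs the
same pipeline in one call.

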