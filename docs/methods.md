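# Methods

This note records the modelling choices, defaults and limitations of the
package in one place.  Empirical statements below are limited to what the
test suite and `scripts/acceptance.py` themselves compute.

## Study design and the response

The unit of analysis is the site-month.  A daily stranding density of at
least 1 jellyfish m⁻² defines an outbreak day; monthly counts of outbreak
days (May–September, four sampling years) are the response.  A complete
design therefore has 20 records per site.  The daily-to-monthly reduction
of environmental covariates is the monthly mean of the daily series; this
is a declared convention of the package (value-on-outbreak-days would be an
alternative), applied consistently in simulation, fitting and the
bootstrap.

Month (integer 5–9) and year (calendar year) enter the linear predictor as
single linear terms.  Raw-year coding makes the intercept an extrapolation
to year 0, so intercept and year are individually weakly identified (wide,
strongly anti-correlated posteriors) while their fitted combination is well
behaved; coefficients on environmental covariates are unaffected.
Covariate standardization is available but off by default, keeping
coefficients on natural scales (per °C, per cm s⁻¹, per km).

## Latent field

The spatial field lives on a Delaunay triangulation built from a
triangular lattice covering the site bounding box (default edge 40 km)
plus a coarser buffer ring (default 80 km wide, 120 km edges) whose
vertices absorb the boundary artefacts of the SPDE precision; no separate
boundary correction is applied.  Sites map to the three vertices of their
containing triangle with equal thirds by default (vertex averaging);
barycentric weights are available and reproduce linear functions exactly,
which the tests exploit as an identity check.

The ν = 1 Matérn precision uses the standard finite-element construction
with a lumped (diagonal) mass matrix, rescaled so interior marginal
variances equal σ_w²; the correlation range is ρ = √8/κ, the distance at
which correlation falls to ≈ 0.1.  A dense-inversion oracle on a fine
regular mesh verifies the implied correlations against the analytic Matérn
to within 0.05 for κh ∈ [0.5, 3].  Temporal evolution is a stationary
AR(1) with innovation precision Q_s and a 1/(1−a²)-scaled start; the time
index enumerates (year, month) pairs chronologically, so the September→May
gap is treated as a single AR step — a simplification shared by the model
the package emulates.  Q_s is constant over time.

## Inference

The backend ("laplace") is an empirical-Bayes integrated-Laplace scheme:

* Given hyperparameters θ = (log κ, log σ_w², atanh a, log σ_t²), the
  latent vector (β, ζ, ε) has a log-concave posterior whose mode is found
  by Newton iterations with sparse LU factorizations (SuperLU, symmetric
  mode, no numerical pivoting, so log-determinants come from the U
  diagonal).
* The Laplace-approximate marginal likelihood plus weak Gaussian priors on
  θ is maximized by Nelder-Mead with an explicit initial simplex (step 0.6
  on internal scales; the default proportional simplex degenerates at
  coordinates near zero).
* β summaries are Gaussian (mode and marginal SDs from columns of
  Q_post⁻¹).  Hyperparameter summaries come from a Gaussian (Laplace)
  approximation on internal scales — numerical Hessian, 4000 transformed
  draws — giving asymmetric intervals on the natural scales (σ_w², ρ, a,
  σ_t²).
* Priors: N(0, 100) per β; log κ ~ N(log κ_init, 2²); log σ_w² ~ N(0, 3²);
  atanh a ~ N(0, 2²); log σ_t² ~ N(−2.3, 3²).  These are proper but weak;
  flat priors are avoided because they break the marginal-likelihood
  machinery.

The σ_t² term is interpreted as an iid observation-level log-rate variance
("extra-Poisson" variation) and is on by default; parameter-recovery
harnesses disable it to isolate β recovery.  The accuracy contract of the
backend is statistical (recovery of known truth within posterior
uncertainty; 95% CI coverage ≥ 80% over 20 replicated studies at ~100
sites × 20 months), not numerical identity with any other software.

Validation follows a seeded 70/30 site split (round(0.7·n) calibration
sites).  Predictive intervals combine the Gaussian posterior of each
linear predictor with Poisson sampling (and optional iid draws); held-out
coverage of ~0.95–1.0 on well-specified simulations is verified in the
tests.  Predictions for the bootstrap are plug-in (posterior means of β
and ζ); posterior-uncertainty draws are available in `predict` but not
propagated through the bootstrap by default.

## Environmental bootstrap

Decomposition: for each calendar day, the mean and sample SD of the
15-day window centred on it, pooled across all years (edge days repeat the
boundary observations so the pool stays at 15 × n_years values).  The
window width is configurable (9–31 days is the sensible range).
Residuals are (x − mean)/SD, with zero-SD days mapped to residual 0 and
logged.  Interchangeability diagnostics: the per-variable decorrelation
time (first non-positive lag of the biased-estimator ACF, pooled over
site-year segments) and a windowed skewness index m₃/m₂ (1/n moments)
checked for correlation with the smoothed mean.

Randomization: blocks are built within each year's season (never spanning
the winter gap; trailing short blocks are kept) and the pooled block list
is permuted once per replicate, identically for every variable and site —
same-day cross-variable and cross-site correlations are therefore
preserved exactly, which the tests assert to machine precision.
Reconstruction rescales by the SD and mean of the receiving calendar
position.  In deterministic mode the climatological-mean series is
permuted in the same blocks while residuals and the SD profile stay in
place.  Because standardized residuals have only approximately zero mean,
the replicate-average day equals the climatology plus a small
finite-sample offset; the conservation tests anchor on the exact
permutation expectation and separately verify the offset is Monte-Carlo
noise around zero.

Per replicate, predictions are computed for every (site, year, month) of
the fitted period; monthly maxima over sites and years are taken on
Poisson draws of the predicted rates (so maxima are integers, like
observed outbreak-day maxima), while per-site SDs are computed on the
rates themselves to keep the forcing contrast free of response noise.
Desk-scale default is 500 iterations; the full-scale 10000 is a config
value.

## Extremes and the forcing contrast

The GEV is fitted by maximum likelihood to per-replicate monthly maxima
(May and June reported by default).  Maxima are small integers; the
continuous GEV is fitted to them directly, with an optional uniform jitter
flag to break ties — the discreteness distortion is acknowledged, not
corrected.  Return levels use the closed form with an explicit Gumbel
branch below |ξ| < 1e-8; the CDF/return-level inversion holds to 1e-10 by
construction and is tested.

The deterministic-vs-stochastic contrast pairs per-site sample SDs
(ddof=1) across replicates by (site, year, month) and applies the Wilcoxon
signed-rank test: W⁺ with the exact rank-sum null (DP recursion) for
tie-free |differences| and n ≤ 25, otherwise the normal approximation with
continuity and tie corrections; zero differences are dropped and counted.
Two-sided by default.

## Synthetic data: what it emulates and what it does not

The generator produces ~60–241 sites along a 1-D, 500 km coastline
(planar km coordinates, Euclidean distances), four canyon heads, and daily
series that are smooth seasonal curves plus AR(1) anomalies correlated
across variables (given SPD matrix) and sites (exponential decay, 100 km
default range).  Default regression coefficients follow the magnitudes a
coastal stranding study reports (e.g. −0.02 per °C SST, −0.006 per km
canyon distance); the spatial range defaults to 50 km and σ_w² ≈ 0.44.
Seasonal amplitudes, anomaly SDs and the anomaly AR coefficient (0.7) are
the package's own choices of realistic magnitudes.

Passing tests on these data show that the machinery is correct — not that
any real coastline behaves this way.  In particular, which forcing
component dominates the default synthetic system is a consequence of the
chosen amplitudes (the default conditions put more predictive variance in
the anomalies); the direction-detection property is therefore tested on a
system with planted deterministic dominance, where the contrast must and
does come out deterministic > stochastic.  Not emulated: realistic
oceanography (fronts, upwelling), lon/lat geodesy, coastline-constrained
(non-convex) meshes, observation error in stranding counts, and
within-season gaps in sampling.

## Numerical details and degenerate inputs

* λ overflow is guarded by clipping η at ±30 before exponentiation.
* Sparse factorizations use MMD ordering; SPD inputs keep the U diagonal
  positive, and |·| guards the log-determinant regardless.
* Collinear sites, sites outside the mesh (named in the error), duplicate
  (site, date) or (site, year, month) keys, non-PD correlation matrices,
  out-of-season dates, |a| ≥ 1, even smoothing windows, all-equal GEV
  samples and all-zero Wilcoxon differences raise explicit errors.
* Exact covariate collinearity reports VIF = ∞ with a warning rather than
  crashing; zero-variance validation observations report an undefined
  correlation with a note.
* Seeds: a single master seed spawns independent per-stage streams
  (SeedSequence), so stages can be rerun or resumed without correlating
  their randomness; identical seeds give bit-identical CSV outputs (floats
  are written with %.17g).

## Problem sizes used by the checks

The replicated-recovery study uses 20 datasets of ~100 sites × 20 months
on a ~80-vertex mesh; the bootstrap checks use 10 sites × 7 seasons × 500
replicates; the forcing contrast uses 25 sites × 500 iterations; GEV
self-recovery uses 10⁴ draws.  These sizes are the package's defaults for
its own verification runs and keep a full check well under typical desk
runtimes while leaving the statistical assertions comfortably powered.
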