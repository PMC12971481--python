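# Methods

`avitwin` implements the model-updating engine of a daily "digital twin" of bird
spatiotemporal distributions driven by audio-based citizen-science detections.
This note documents the model, the estimation procedures, the synthetic study
conditions, and the numerical choices, in the package's own terms.

## The factorized detection model

A recording stream consists of records indexed by *i*, each with a timestamp
*t_i* (year, day of year, minute of day), a 1-ha grid cell *c_i* with latitude
lat(*c_i*), a recording type *r_i* ∈ {direct, interval, point} and log-duration
*x_i* = ln(duration in minutes). For species *j*, the binary detection *Y_ij*
(classifier confidence ≥ 0.90 upstream) is modelled as

    P[Y_ij = 1] = m_j(c_i, t_i) · s_j(c_i) · d_j(t_i, r_i, x_i)

— the species must have arrived and not departed (*m*, migration), the cell
must be part of its distribution (*s*, spatial occurrence), and it must
vocalize detectably (*d*, detection).

**Migration** is a six-parameter curve:

    m_θ(lat, day) = min{ Φ((day − θ_SM − θ_SL·lat)/θ_SI),
                         1 − Φ((day − θ_AM − θ_AL·lat)/θ_AI) },

with Φ the standard-normal CDF; θ_SM/θ_SL give the latitude-dependent mean
spring arrival day, θ_SI the spread of arrival (days), and the A-parameters
the autumn analogues. Residents have m ≡ 1. Spread parameters are floored at
0.5 days to avoid degenerate step curves from noiseless fits.

**Prior fits.** The prior detection model d^PAM (per 1-minute passive acoustic
segment) is a logistic regression on first and second sin/cos harmonics of the
day-of-year and time-of-day fractions (day scaled as (day−1)/365, leap day
wrapping to 0; minute as minute/1440), fitted only inside each site-year's
presence window — between the ⌈0.05n⌉-th and ⌈0.95n⌉-th detection in
chronological order — so it captures vocal activity conditional on presence.
The prior migration parameters come from per-(year, latitude-zone) 5%/95%
order-statistic "first"/"last" days (groups with < 50 occurrences dropped),
OLS-regressed on latitude; the spreads are one fourth of the 95% OLS
prediction-interval width averaged over zone latitudes. Both fits use
statsmodels; degenerate inputs (single-class response, single zone, perfect
separation) raise an explicit `FitError` rather than fall back silently.

## Posterior updaters

**Detection translation.** App recordings differ from 1-minute passive
segments, so the detection component is translated per species with a probit
model, d^MK = Φ(α + β_r·x + γ·Φ⁻¹(d^PAM)), with independent Normal(0, 5²)
priors on all five coefficients. The MAP is found by L-BFGS-B with analytic
gradients from a zero start (records are canonically sorted first so the
floating-point reduction, and hence the optimum, is independent of input
order), followed by a Newton polish with a finite-difference Hessian; the fit
fails loudly if the gradient sup-norm stays above 1e-3. The MAP is used as a
plug-in and refreshed once per year on all accumulated data; no posterior
variance is propagated.

**Migration update.** Parameters are reset to the prior each 1 January and
refitted within the year by minimizing the Bernoulli deviance (spatial and
detection components fixed) plus λ·f(θ̃), where the functional penalty

    f(θ̃) = ∫∫ [m_θ̃(lat, day) − m_θprior(lat, day)]² d lat d day

is approximated by a midpoint sum over a uniform grid (default latitudes
59.5–70.0 step 0.5°, days 1–365; a degenerate axis contributes measure 1) in
degree·day units, with λ = 0.01 interpreted on that scale. Penalizing the
curve rather than the raw parameters tolerates the strong intercept–slope
trade-off (over a narrow latitude span, very different parameter vectors give
near-identical curves) while keeping the curve's shape anchored. Spreads are
optimized on the log scale; box constraints (means ±400 days, slopes ±6
days/degree, spreads in [0.5, 90] days) keep the optimizer in the numerically
sane region without binding in practice. Zero records return the prior
object unchanged.

**Spatial update.** Each 1-km² cell c₀ is updated independently by maximizing
a local log-likelihood — Bernoulli terms of all records weighted by a Gaussian
kernel K(c, c₀) = exp(−τ·dist² / 2) of the distance between cell centers —
plus the log-density of a Normal(prior mean, prior sd) prior truncated to
[0, 1]. τ = 1/2.5² km⁻² by default, with the kernel truncated to exactly zero
beyond 7.5 km (three kernel sd); τ = 0 means every cell sees the pooled
likelihood (and no truncation). Posterior spread is the Laplace value
(−ℓ''(ŝ))^(−1/2), falling back to the prior sd if the curvature is
non-negative. The reference implementation (`update_cell`) is a bounded scalar
minimization to 1e-9; the production path (`update_raster`) solves all cells
at once by a safeguarded Newton iteration on the strictly concave objective,
collapsing the records into per-cell power sums via an exact geometric-series
expansion of the non-detection terms (truncation error < 1e-12; records with
m·d > 0.9 use a dense exact path). The two agree to ~1e-8.

**Resolution reconciliation.** Prior surfaces live on the 1-ha grid; the
update runs at 1 km². Fine means and variances are block-averaged down
(nodata-aware), and probit-scale prior maps can be converted to
probability-scale moments by 64-node Gauss–Hermite quadrature (mean and sd of
Φ(Z)). The coarse posterior is mapped back by shifting the fine priors on the
probit scale by the unique δ solving mean_i Φ(Φ⁻¹(prior_i) + δ) = coarse
posterior: within-block ranks of the prior are preserved exactly and the block
mean matches to 1e-6. A `literal=True` variant that instead shifts the coarse
posterior toward the fine priors (which yields a block-constant surface) is
kept for comparison only, because it discards the prior's local geometry.

## Evaluation and site selection

The walk-forward evaluation mimics nightly operation: for each schedule day T,
the migration and spatial posteriors are refitted on all records with day ≤ T
(the translation having been pre-fitted on a burn-in season) and records in
(T, T+window] are scored by both the prior model and the posterior model.
Predictions are pooled across all test windows before computing one
Mann–Whitney AUC (ties counted half) per species per model; species under a
detection-count threshold are excluded. The relative gain statistic is
100·(AUC_post − AUC_prior)/(AUC_prior − 0.5), rounded to integer percent.

Validation-site selection scores a candidate cell for species *j* by
f_j = |posterior − prior|, discounted by a penalty product over previously
chosen sites: g = γ·1(m at chosen site ≥ 0.75)·exp(−(τ/2)·[(Δprior)² +
(Δposterior)²]) with γ = 0.95 and τ = 400 (a 0.05-sd Gaussian kernel in
probability space); the day's total utility sums migration-gated species
utilities. Sites are picked greedily — first within 50 km of the volunteer's
home, then within 10 km of the first pick, all ≥ 1 km from every earlier
site, ties broken by (utility, row, col) — with the history updated after
each pick, so same-day picks penalize each other. The exponent is negative:
only that sign yields a kernel that is large when scenarios are close and
bounded by γ, which is what the penalty is for.

## Synthetic study conditions

The generator builds desk-scale worlds with known truth; its defaults are the
package's study conditions.

- **Grid**: 200×200 one-ha cells (20×20 km, coarse 20×20), rows mapped
  affinely to latitudes 62→60 °N.
- **Species**: 10 per world, 80% migratory; spring arrival at 60 °N uniform in
  days 100–140, latitude slope 0.5–2 days/degree, arrival spread 3–8 days;
  autumn departure 240–280 with spread 6–12 days.
- **True occurrence fields**: Gaussian-filtered white noise (σ = 4 km) mapped
  through Φ and clipped to [0.02, 0.98]. The kernel precision τ = 1/2.5² fixes
  the method's spatial resolution; fields varying well below that scale are
  unresolvable by construction, so the synthetic truth is generated at a
  coarser correlation length than the kernel — in the real system the fine
  structure is carried by the prior's habitat detail, which upsampling
  preserves, while the update corrects regional errors.
- **Detection**: per-minute vocal detection intercepts uniform in
  (−2.8, −1.8) (a few percent per minute); translation truth with α ∈ (0, 0.6),
  duration slopes β_direct ∈ (0.3, 0.8), γ ∈ (0.6, 1.0). A 50-day season then
  yields roughly 1–4 thousand detections per species from ~27 k recordings —
  the desk-scale analogue of the well-observed species in a national stream.
- **Observers**: 200 users at uniform random homes; 70% direct (Poisson 2
  recordings/day, log-normal durations with median ~0.55 min, start times
  weighted by 1 + b·(expected vocal activity) with trigger bias b = 2),
  15% interval users (1-min segments every 10 min for 1–6 h), 15% point
  counters (5-min recordings at fixed stations). All generators are pure
  functions of (inputs, seed); timing and detection draws use spawned,
  independent seed streams.
- **Prior perturbation (signal world)**: prior spatial mean =
  Φ(Φ⁻¹(truth) + smooth probit noise, σ_spatial = 5 km, sd 1.2); prior sd
  layer constant 0.15; migration means shifted by Normal(0, 10²) days. Zero
  shifts reproduce the truth exactly (null world). The shift magnitudes encode
  a prior that is substantially wrong regionally and misdates migration by
  about a week and a half — the regime the twin exists to correct.

What the generator does **not** emulate: classifier errors (detections are
drawn at the post-threshold level), user heterogeneity and preferential
targeting of novel species, geography (roads, water, habitat maps), longitude
effects, and within-season re-departures. Passing tests therefore show the
estimators recover the truths of this idealized observation process at desk
scale, not that the full system performs identically on national data.

## Walk-forward problem sizes and observed behaviour

The end-to-end cycle used in the test suite runs the season days 113–162 with
weekly refits and a 7-day forecast window, the translation pre-fitted on an
identical-conditions burn-in season the year before, and a 100-detection
inclusion threshold. One full simulate+update+evaluate cycle takes ~15 s on a
single CPU. Under the null world the mean next-window AUC difference stays
within ±0.01 of zero; under the signal world the posterior improves the mean
AUC by ≈ 0.05–0.08 (prior ≈ 0.72 → posterior ≈ 0.79 across seeds), with the
spatial correction contributing most of the gain.

## Numerical conventions and edge cases

- Φ/Φ⁻¹ are scipy's `ndtr`/`ndtri`; the mutual-inverse identity holds to 1e-9
  for z ≤ 5.5 (above that, float64 cannot represent the upper-tail probability
  accurately enough for any implementation to do better than ~1e-8).
- Probabilities entering logs or Φ⁻¹ are clamped to [1e-9, 1−1e-9] (or 1e-12
  inside likelihoods) with a logged warning.
- Grids are 0-based, row-major, north-west origin; the fine grid nests exactly
  10×10 in the coarse grid. Distances are planar Euclidean in km between cell
  centers; recording latitude is carried separately in decimal degrees.
- Rasters are exchanged as ESRI ASCII grids (km coordinates, NODATA −1) — a
  plain-text format readable anywhere; streams as UTF-8 CSV written at 17
  significant digits so write/read round trips are lossless.
- Selection, updating and evaluation are deterministic given data and seeds;
  rerunning a configuration reproduces result files byte-for-byte.

## Known limitations

- The spatial updater estimates a kernel-smoothed surface; structure below
  ~2.5 km is attenuated, and in data-sparse regions the posterior reverts to
  the prior. The 0.15 prior sd is a global constant in the synthetic worlds,
  not an honest per-cell uncertainty.
- The migration intercept/slope pair is weakly identified over narrow latitude
  spans; only the curve (not individual parameters) should be interpreted.
- The translation model assumes detection depends on duration and type only
  through the linear probit term, and ignores per-user heterogeneity.
- Walk-forward AUCs pool predictions across windows, so species with strong
  within-season detection trends can show AUC differences driven by timing
  rather than space.
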