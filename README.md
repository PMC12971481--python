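# avitwin

A daily-updated "digital twin" of bird spatiotemporal distributions, driven by
streams of audio-based citizen-science detections.

Smartphone apps that record bird sound and classify it with machine learning
produce a continuous stream of presence/absence detections with known effort
(location, time, recording type, duration). `avitwin` turns such a stream into
continuously updated occurrence maps: it starts from prior models built on
long-term data and re-estimates, every night, where each species is and when
it arrives — then measures whether the updated model actually predicts
tomorrow's detections better than the prior did. The package is aimed at
quantitative ecologists working on detection/occupancy models, data
integration for species distribution modelling, and adaptive survey design.

## The model

For recording *i* and species *j*, the probability of a detection factors into
three components:

    P[Y_ij = 1] = m_j(c_i, t_i) · s_j(c_i) · d_j(t_i, r_i, x_i)

- **Migration** m: a six-parameter phenology curve,
  m_θ(lat, day) = min{Φ((day − μ_S(lat))/σ_S), 1 − Φ((day − μ_A(lat))/σ_A)}
  with latitude-linear spring-arrival and autumn-departure means (m ≡ 1 for
  residents).
- **Spatial occurrence** s: a per-cell probability surface on a 1-ha grid.
- **Detection** d: a periodic logistic model of per-minute vocal detection
  (harmonics of day-of-year and time-of-day), translated to app recordings by
  a probit model in recording type and log-duration:
  d^MK = Φ(α + β_r x + γ Φ⁻¹(d^PAM)).

Three Bayesian updaters consume the stream: a MAP fit of the translation
coefficients under Normal(0, 5²) priors (refreshed yearly); a year-specific
MAP update of θ under a *functional* prior penalizing
λ∫∫(m_θ̃ − m_θ)² (λ = 0.01), which shrinks the curve rather than the
parameters; and a per-cell local-likelihood update of s, weighting records by
a Gaussian kernel of distance (τ = 1/2.5² km⁻², truncated at 7.5 km) under a
truncated-normal prior, with Laplace posterior spreads. A walk-forward
evaluator refits posteriors on data up to day T and scores predictions for
(T, T+window] by Mann–Whitney AUC, and a utility-based selector picks
validation survey sites where prior and posterior disagree most, avoiding
repeated scenarios and respecting travel-distance constraints.

Because national-scale inputs cannot ship with a package, a first-class
synthetic-data module generates desk-scale worlds with known ground truth —
smooth occurrence fields, phenology curves, vocal-activity cycles, and an
observer population emitting direct/interval/point recordings with
vocalization-triggered timing bias — so every estimator can be tested against
the truth that generated its data.

## Worked example

Run a full synthetic cycle — build a world, perturb its priors, fit the
detection translation on a burn-in season, then walk-forward-evaluate a
50-day season of ~27,000 recordings by 200 users for 10 species:

```python
from avitwin.pipeline import RunConfig, run_evaluation

results = run_evaluation(RunConfig(seed=1), "out")
print(results.round(3))
```

```
  species_id  n_detections  auc_prior  auc_posterior  delta
0       sp00          1652      0.727          0.764  0.037
1       sp01          3487      0.735          0.741  0.006
2       sp02          2076      0.725          0.836  0.111
3       sp03          1689      0.728          0.771  0.043
4       sp04          1382      0.718          0.807  0.089
5       sp05          3539      0.697          0.763  0.066
6       sp06          1919      0.760          0.795  0.035
7       sp07           818      0.778          0.831  0.054
8       sp08          1919      0.748          0.782  0.034
9       sp09          1053      0.751          0.836  0.085
```

Each row is one species; `auc_prior` is the next-window AUC of the static
prior model, `auc_posterior` that of the nightly-updated twin, pooled over all
forecast windows. Here the prior was deliberately perturbed away from the
truth (regionally shifted occurrence, migration misdated by ~10 days), and the
twin recovers most of the lost skill: mean AUC rises from 0.74 to 0.79. With
an unperturbed prior (`RunConfig(seed=1, spatial_shift_sd=0, migration_shift_days=0)`)
the mean difference stays within ±0.01 — updating does not degrade an already
correct model. `run_evaluation` also writes `results.csv` and a
`run_meta.json` sidecar (config hash, seed, stream sizes) to the output
directory; identical configs reproduce identical files byte-for-byte.

The same operations are available from a shell:

```
avitwin simulate     --seed 1 --out-dir out   # stream CSV + prior/truth rasters
avitwin fit-priors   --seed 1 --out-dir out   # prior detection fit from PAM data
avitwin update-daily --stream out/stream.csv --day 143 --seed 1 --out-dir out
avitwin evaluate     --seed 1 --out-dir out   # the walk-forward table above
avitwin select-sites --seed 1 --out-dir out   # validation-site assignments
```

Rasters are written as plain-text ESRI ASCII grids (km coordinates,
NODATA −1); streams and parameter tables as CSV.

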