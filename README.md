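# habsens

Simulation-based sensitivity analysis of habitat-selection estimators.

Telemetry studies estimate how animals select habitat by contrasting the
locations an animal used with locations that were available to it. The two
workhorse methods — resource-selection analysis (RSA, a logistic regression
of used vs. uniformly sampled available points) and integrated
step-selection analysis (iSSA, a conditional logistic regression of observed
vs. kernel-sampled steps) — make different assumptions about availability
and temporal dependence, and their estimates are known to react to both the
fix interval of the tracking device and the spatial autocorrelation of the
landscape. `habsens` provides a complete in-silico laboratory for
quantifying those sensitivities: it generates landscapes with controlled
autocorrelation, simulates movement with *known* selection coefficients,
degrades the tracks the way real tag programmes do (rarefaction, thinning,
battery-limited truncation), and measures what each estimator recovers.

It is aimed at movement ecologists and method developers who want to check,
before interpreting field estimates, how much of an estimated selection
coefficient is biology and how much is sampling design.

## Model

Movement is a stepping-stone process on a square raster with three
covariates: a continuous surface `elev`, a binary habitat indicator `hab`
(a fractional-Brownian field thresholded at 0.5), and distance to the
landscape centre. At every raw time step the animal leaves its cell with
probability `p_move = 0.3`; conditional on moving it picks the von Neumann
neighbour `j` with probability

    P(j | move) ∝ exp(ω_elev · elev_j + ω_hab · hab_j + ω_cent · dist_j)

with defaults ω_elev = 2 (preference), ω_hab = −2 (avoidance) and
ω_cent = −0.01 (homing). Landscape roughness is controlled by the
fractional dimension of the variogram γ(h) = h^d, with d ∈ {0.01, 0.1, 1}
spanning no → intermediate → high spatial autocorrelation.

The estimators all target the exponential habitat-selection function
w(z) = exp(β₁z₁ + … + β_m z_m):

* **RSA** — used points vs. 20× available points sampled uniformly from the
  minimum convex polygon of the track; binomial GLM with logit link.
* **wRSA** — the same design, but each used point is down-weighted by the
  track's effective sample size n_eff = n(1−ρ)/(1+ρ), where ρ is the
  per-interval position autocorrelation of a fitted first-order
  autoregressive (discrete Ornstein–Uhlenbeck) model.
* **iSSA** — observed steps vs. 20 available steps per stratum drawn from a
  fitted gamma (step length) × von Mises (turning angle) movement kernel,
  fitted by conditional logistic regression with optional `log(sl)` and
  `cos(ta)` movement-adjustment terms.

Significance is read off the 95% Wald interval (CI excludes zero), and the
experiment layer summarises replicate spread and fraction-significant over
the factorial grid (autocorrelation × sampling interval × method).

## Worked example

```python
import habsens as h

landscape = h.make_landscape_set(size=256, fract_dim_elev=0.1,
                                 fract_dim_hab=0.1, seed=1)
params = h.SelectionParams(omega_elev=2.0, omega_hab=-2.0,
                           omega_cent=-0.01, p_move=0.3)
track = h.simulate_track(landscape, params, n_raw_steps=10_000_000,
                         keep_every=100, seed=2)
sample = h.truncate_track(h.thin_track(track, 10), n_max=1000)

fits = [h.fit_rsa(sample, landscape, seed=3),
        h.fit_wrsa(sample, landscape, seed=3),
        h.fit_issa(sample, landscape, seed=3)]
tidy = h.results_to_tidy(fits)
print(tidy[["method", "covariate", "estimate", "se", "significant"]]
      .to_string(index=False, float_format="%.3f"))
```

```
method covariate  estimate    se  significant
   RSA intercept    -2.682 0.141         True
   RSA      elev     0.126 0.264        False
   RSA       hab    -2.381 0.150         True
  wRSA intercept    -7.249 1.338         True
  wRSA      elev     0.127 2.494        False
  wRSA       hab    -2.381 1.466        False
  iSSA      elev     2.152 0.312         True
  iSSA       hab    -2.182 0.152         True
  iSSA    log_sl     0.074 0.050        False
  iSSA    cos_ta     0.019 0.047        False
```

One 1000-fix track at an intermediate sampling interval on a moderately
autocorrelated landscape: iSSA recovers both simulated preferences with the
right signs and magnitudes near the inputs (+2 / −2); RSA finds the habitat
avoidance but the elevation signal is washed out by its static availability
domain at this interval; wRSA reaches the same point estimates as RSA but —
having down-weighted the autocorrelated fixes to an effective sample size of
a few dozen — correctly reports that this track carries too little
independent information to call either coefficient significant.

The factorial experiment behind such single fits is driven by
`ExperimentConfig`/`run_grid`/`summarize` (or the `habsens experiment` CLI),
which record, per method × covariate × autocorrelation level × thinning
factor, the replicate spread of the estimates and the fraction of
significant fits.

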