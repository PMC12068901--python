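# Methods

This note records the modelling and numerical choices behind `habsens`, what
the synthetic data do and do not emulate, and the limitations a user should
keep in mind when carrying conclusions over to field data.

## Landscape generation

Covariate surfaces are two-dimensional fractional Brownian fields with
intrinsic variogram γ(h) = h^d, where the "fractional dimension" d ∈ (0, 2]
controls roughness. They are synthesised by circulant embedding: on a
doubled periodic grid the stationarised covariance C(h) = H^d − h^d (H the
maximum torus lag) is Fourier-transformed to spectral weights, tiny negative
eigenvalues are clipped, and one inverse FFT of spectrally weighted white
noise yields the field, which is cropped to the target size to remove
wrap-around and min–max rescaled to [0, 1]. Embedding the variogram itself,
rather than an asymptotic power-law spectrum f^−(d+2), matters at small d:
on a finite grid the power-law route produces a log-correlated field whose
rook-weight Moran's I stays near 0.8 even at d = 0.01, whereas the
variogram embedding gives the intended behaviour — measured Moran's I of
about 0.04 / 0.35 / 0.98 at d = 0.01 / 0.1 / 1, i.e. genuinely
uncorrelated, intermediate and smooth landscapes. Only the *ordering* of
autocorrelation across d is contractual; absolute Moran's I values depend
on grid size.

The binary habitat layer thresholds an independent field at values strictly
greater than 0.5, which leaves ~50% habitat on average. Because min–max
rescaling puts the threshold at the midpoint of the two grid extremes, the
per-seed habitat fraction scatters around 1/2 (SD ≈ 0.08–0.13 at desk
sizes, wider for smoother fields); the mean is centred. The distance layer
is the Euclidean distance to the landscape centre, unstandardised; for even
grid sizes the centre is the corner point shared by the four central cells
(so the minimum distance is √2/2 rather than 0).

Seeding uses one master seed expanded into named substreams
(`seeding.substream`), so e.g. the elevation layer of a landscape replicate
is reproducible without regenerating anything else, and changing one
layer's roughness leaves the other layer's realisation untouched.

## Movement simulation

The stepping-stone process is exactly the two-stage rule described in the
README: an unconditional leave probability `p_move` (default 0.3, not
covariate dependent) followed by a softmax choice over the in-grid von
Neumann neighbours with weights exp(ω·z). Design choices:

* Boundary rule: out-of-grid neighbours are removed and the move
  distribution renormalised; P(stay) remains 1 − p_move. With homing at
  full scale the boundary is effectively unreachable, so this rule only
  matters in desk-scale runs.
* The current cell does not enter the weight comparison; staying is decided
  before the neighbour softmax.
* Start locations are drawn uniformly from the central square with 20% of
  the side length (the [800, 1200]² square on a 2000-cell grid).
* Tracks are rarefied during simulation (every 100th raw position by
  default), further thinned by k ∈ {1, 10, 100} — interpreted as thinning
  the already-rarefied series, so the three intervals span two orders of
  magnitude of biological sampling rates — and truncated to the first 1000
  fixes to emulate a fixed battery budget. The pipeline order is fixed:
  thin, then truncate, so every interval keeps the same number of fixes.
* The raw-step loop is numba-compiled (~10⁷ steps/s on one core); the
  sequential semantics are normative and the pure-Python
  `neighbor_distribution` is the reference for single-step probabilities.

The experiment default of 10⁷ raw steps per track (not fewer) is chosen so
that the coarsest thinning factor still yields the full 1000-fix budget
(10⁷ / 100 rarefaction / 100 thinning = 1000); at the compiled loop's
throughput this costs well under a second per track.

Homing strength ω_cent = −0.01 is a paper-scale setting: the stationary
home-range radius scales like 1/|ω_cent| (hundreds of cells). Desk-scale
containment diagnostics therefore use a proportionally stronger pull; the
experiment grid keeps −0.01 and relies on the boundary rule, which slightly
compresses the largest excursions on 256-cell grids.

## Steps and the movement kernel

Turning angles are signed differences of successive step bearings
(counterclockwise from +x, wrapped to (−π, π]); the first step of a track
has no defined angle and never forms a stratum. Zero-length steps — the
discrete simulator can return to a cell within one interval — get a floor
displacement of half a cell width (`ZERO_STEP_SL = 0.5`) before gamma
fitting, and their turning angles are treated as missing (drawn uniformly
where a value is required). Gamma parameters are scipy maximum likelihood
with the location pinned at zero; the von Mises concentration solves
A(κ) = mean resultant length by Brent's method on exponentially scaled
Bessel ratios, capped at κ = 500 for degenerate (all-equal) samples.
Available steps start at the used step's start point, with lengths from the
fitted gamma and turning angles from the fitted von Mises applied to the
previous bearing; end points off the grid are redrawn (up to 100 rounds)
and finally clamped with a logged warning. Covariates are read at the end
cell by nearest-cell lookup — no along-step integration.

## Estimators

* **RSA.** Availability defaults to the 100% minimum convex polygon of the
  used points (bounding box and full-landscape domains are options, and the
  domain kind is recorded in the fit metadata, because the choice of domain
  is itself a known sensitivity of RSA). Exactly 20 available points per
  used point. The GLM is statsmodels' binomial family with logit link;
  fits that fail or separate are flagged `converged=False`, never raised.
* **wRSA.** The weighting is a deliberately transparent single-timescale
  scheme: a pooled AR(1) fit to the x/y position series gives the lag-one
  correlation ρ, the effective sample size is n(1−ρ)/(1+ρ), and every used
  row carries the uniform weight n_eff/n in the weighted likelihood
  (available rows keep weight 1). This captures the mechanism — temporal
  autocorrelation deflates the information content of a track, and
  coarsening the interval restores it — without continuous-time model
  selection, kernel home ranges or per-fix optimal weights, which are out
  of scope. With ρ = 0 the wRSA fit is exactly the RSA fit.
* **iSSA.** The conditional logistic regression is implemented in-package:
  Newton iteration on the stratum-conditional log-likelihood with analytic
  gradient and Hessian, step-halving, convergence at max|grad| < 1e−8 or
  relative log-likelihood change < 1e−10, at most 100 iterations. No
  intercept (absorbed by strata). Covariates without within-stratum
  variation anywhere are reported as unidentifiable (estimate 0, infinite
  SE). Movement-adjustment terms log(sl) and cos(ta) are on by default and
  reported alongside the habitat coefficients.
* Significance is the 95% Wald interval excluding zero, per coefficient,
  with no multiple-testing correction — matching the fraction-significant
  summary the experiment reports. Simulated ω and estimated β are related
  but not equal (scale dependence of discrete-choice coefficients), so the
  analysis surface is signs, spreads and significance fractions, not
  magnitude equality. One exact magnitude check does exist: conditional
  logit on the simulator's true move-choice sets (the four neighbours of
  each move, for which P(j|move) is exactly softmax(ω·z)) is consistent
  for ω, and the test suite verifies recovery of (2, −2) within 2 SE in
  ≥90% of replicates. Stay decisions are excluded from those strata
  because the leave probability is covariate-independent — a five-way
  logit including "stay" would be misspecified.

When tracks are simulated with homing, the distance-to-centre covariate is
deliberately *not* offered to the estimators (it can be requested
explicitly), mirroring the common situation where the centralising driver
of real movement is unmodelled.

## Experiment design and problem sizes

The default grid is desk-scale: 256-cell landscapes, 2 landscape replicates
× 5 tracks per autocorrelation level (0.01, 0.1, 1 for both covariates),
thinning factors 1/10/100, all three methods, homing on, both covariates in
simulation and model. These sizes keep a full grid plus the rest of the
suite within a coffee break on a single core while leaving the qualitative
orderings (spread growing with landscape autocorrelation; long intervals
stabilising estimates on smooth landscapes; wRSA significance rising with
the interval) clearly resolved. `ExperimentConfig.paper_scale()` switches
to 2000-cell landscapes and 10 × 20 replication — a cluster-sized job.
Every cell derives its own seed from the master seed via named substreams,
cells are written to per-cell CSVs as soon as they are computed, and
resuming an interrupted grid reproduces the identical table. Summary SDs
use the n−1 denominator; non-convergent fits are excluded from both sides
of the fraction-significant ratio and counted in `n_excluded`.

## What the synthetic data do not emulate

No GPS measurement error, no irregular fix intervals in the simulator (a
separate GPS-style fixture generator with jittered timestamps exists purely
for I/O and resampling tests), no behavioural states, no inter-individual
variation, no landscape change over time. Passing tests therefore show that
the estimators behave as expected under a clean, correctly specified
movement process; they do not bound the additional distortions real
telemetry adds. The wRSA implementation is a single-timescale
approximation: tracks whose autocorrelation has multiple timescales (e.g.
position + velocity) will be down-weighted imperfectly. RSA conclusions are
conditional on the availability-domain convention; the MCP default is
recorded per fit so any domain comparison can be recomputed.
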