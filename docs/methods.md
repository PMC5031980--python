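# Methods

This note documents the models implemented in `bluefinhab`, the synthetic
study conditions used to validate them, the numerical choices that matter,
and the limits of what the validation establishes.

## Input model

A *track* is one fish's daily geolocations (lon/lat, WGS84) with a per-day
positional error radius in degrees, as produced by a light-level
geolocation + state-space smoothing workflow upstream of this package.
Gulf occupancy follows the tagging convention: a fish has entered the Gulf
of Mexico once it passes 80.5° W and stays west of that meridian for at
least six consecutive days; occupancy intervals are maximal such runs.

Environmental covariates live on a regular 0.25° grid: SST (°C) and its
8-day variability, chl-a (mg m⁻³), SSH anomaly (cm) and its variability,
eddy kinetic energy (m² s⁻²), Ekman pumping (m s⁻¹), north wind (m s⁻¹),
bathymetry (m, negative down) and rugosity.  Extraction at a daily position
averages each field over grid cells whose centers fall within the day's
error radius (Euclidean in lon/lat degrees; land cells excluded; the
containing cell if none qualify), matches dynamic layers by nearest date (no
temporal interpolation, mirroring the use of 8-day composites), and
log-transforms chl-a and EKE *after* averaging.  Averaging before the log is
a documented choice — the alternative order is not exposed because the mean
of logs changes the covariate's meaning (geometric mean).  The moon
covariate is the illuminated fraction, (1 − cos 2π·age/29.530588)/2 with age
measured from the 2000-01-06 18:14 UT new moon; it depends on the date only.

## Correlated-random-walk pseudo-absences

Each source track yields an empirical step-length distribution (great-circle
daily displacements, km) and turning-angle distribution (signed heading
changes, wrapped to (−π, π]).  A CRW starts at the source's first position
with the source's initial heading and, each day, draws a step length and a
turning angle independently with replacement (a joint mode that keeps
(length, turn) pairs together is available; the independent draw is the
default since nothing in the protocol requires joint preservation).  Steps
are placed by local-tangent-plane dead reckoning on a 6371-km sphere.  Steps
landing on land or outside the domain are rejected and redrawn up to 50
times, then the heading is reversed for that step; if even the reversed step
is invalid the fish holds position for a day.  Every CRW carries the
source's dates and error radii, so presence and pseudo-absence are sampled
at identical spatiotemporal scales.  Ensembles are 100 CRWs per track;
run *r* of the model ensemble draws one member per track from a named
substream of the master seed, so the draw for (tag, run) is reproducible in
isolation.

## Binomial GAMM

The habitat model is penalized IRLS on a logit link.  Each smooth is a cubic
B-spline basis of dimension 5 (one interior knot), column-centered for
identifiability against the intercept, with a second-order difference
penalty (P-splines); basis dimension 5 reflects the smooth, low-complexity
response shapes expected of thermal and topographic preferences.  The
per-tag random intercept is a block of indicator columns under a ridge
penalty — exactly the working form of a Gaussian random intercept — with its
own smoothing parameter.  Smoothing parameters are chosen by GCV on the
converged working linear model (performance iteration, two outer cycles,
Nelder-Mead on log λ; λ clamped to [10⁻⁴, 10⁸]).  A REML criterion was
evaluated as an alternative and chose comparable penalties, so the simpler
GCV is kept.  Coefficients with |β| > 200 trigger a complete-separation
warning and a refit with penalties inflated 100-fold.

Reported statistics: effective degrees of freedom by the trace of the
influence matrix; AIC = deviance + 2·edf; training AUC; deviance explained;
per-smooth Wald-type χ² tests on the penalized coefficient block using the
Bayesian covariance and the block's rounded edf as degrees of freedom (a
pragmatic analogue of the usual approximate smooth tests — adequate for the
stability fractions it feeds, not a calibrated small-sample test).
Prediction for new fish sets the random intercept to its population mean
(zero on the link scale).  Model selection ranks candidates by AUC, ties
broken by lower AIC.  Cross-validation: stratified random 75/25 splits
(default k = 5; class ratio preserved per fold) or leave-one-calendar-year
out; single-class folds are skipped with a warning.

The published description of this model family calls the response
binary with a "negative binomial link"; for 0/1 data the coherent choice is
a binomial likelihood with logit link, which is what is implemented.

## Spawning-day detection

Night is sun altitude < 0 at the day's position (low-precision solar
ephemeris; the generator and detector share this definition by
construction).  Oscillation cycles are descending zero-crossings of depth
minus its 40-min rolling median during the night, counted only when the raw
depth excursion between adjacent crossings reaches 5 m peak-to-trough —
measuring amplitude on the raw signal rather than the detrended one avoids
the ~40% inflation the rolling-median residual introduces when the window is
near 1.4 cycle lengths.  Ten daily proxies are computed (cycle count, median
night depth, daily max depth, night internal−external temperature excess,
SST, day-of-year, moon fraction, bathymetry, daily displacement, dominant
oscillation period); the set is configuration-driven since the original
proxy definitions are not published in the main text.

Classification is two-class naive Bayes: per-class, per-proxy 1-D densities
(Gaussian KDE with Silverman bandwidth by default; Gaussian and
empirical-frequency families available), an empirical or user prior, and a
0.5 posterior threshold.  Missing proxies contribute likelihood 1, so a day
with no usable proxies scores the prior.  Posteriors are computed in log
space with max-normalization so that extreme class-conditional densities
saturate the posterior instead of underflowing both classes; a zero-variance
training sample gets a floor bandwidth of 5% of its magnitude so neighboring
discrete values (e.g. 22 cycles vs a training set of all-21s) are not
annihilated.  Days are classified independently; no temporal smoothing is
applied.  Transit days (the deep-diving Gulf entry/exit days) are
non-spawning training examples.

## Prediction, thresholds, exposure

Weekly surfaces evaluate the fitted model on all water cells using the
covariate layers nearest the week midpoint; ensemble prediction averages the
retained per-run fits and reports the cellwise sd.  Binary maps use the
smallest score threshold whose empirical false-positive rate on the
validation table is ≤ 5% (configurable; conservative habitat estimates), and
the total-spawning-habitat surface is the cellwise habitat × spawning
product thresholded at the product of the two cutoffs (an intersect-binaries
mode exists; product-then-threshold is the default since the published
procedure multiplies likelihoods before binarizing).  Oil polygons are
matched to weeks by nearest date with no geometric morphing, rasterized by
exact polygon/cell clipping (partial cells count by covered fraction), and
areas accumulate the spherical cell area R²Δλ(sin φ_N − sin φ_S).  Zero
denominators report 0% with a flag.  Movement scale uses per-position
first-passage time (backward + forward first crossings of a circle, linearly
interpolated between daily fixes) and residence time (summing re-entry
episodes separated by ≤ 12 h outside); the radius maximizing the variance of
log FPT marks the dominant scale of area-restricted movement.

## Synthetic study conditions

The generator emulates the statistical structure the analysis assumes, not
Gulf hydrodynamics.  Fields are deterministic mean structures plus
Gaussian-filtered noise (correlation length 1.5°, unit-variance normalized):
SST = 24.5 °C at 24.5° N with a −0.6 °C/° latitude gradient and a +2 °C
warm tongue along a Loop-Current-like polyline that also carries elevated
EKE and SSH variability; chl-a is lognormal with a shelf boost; bathymetry
is a smooth basin (30 m rim to 3800 m center) with a land rim on the west,
north and south and an open eastern boundary for Gulf entry.  chl and EKE
are strictly positive by construction.

Tracks are step-selection walks: one gamma(2, 30 km) step length per day, 24
candidate headings (previous heading + von Mises(κ=1.5) turns), each
candidate weighted exp(strength × score) where the score is the log of a
Gaussian kernel in the preferred covariate, −(x − opt)²/(2w²).  The true
log selection weight is therefore quadratic in the covariate — the quantity
a presence/pseudo-absence logit model estimates in the well-mixed limit,
which is what makes the recovery experiment well-posed.  Land candidates get
weight zero; all-land days reverse heading.  Error radii are lognormal
(median 0.25°, σ=0.35) — the real tags' radii are unpublished, and larger
radii smear extraction enough to blur the recovery experiment's contrast.
The canonical preference is SST, optimum 24 °C, width 1.5 °C, strength 4.5
("strong" preference: the usage-weight ratio between the optimum and water
2 °C away is ≈ e⁴).  Release points sit at 81° W, 25–27.5° N — thermally
neutral water away from the warm tongue, whose flat interior gradients
otherwise trap transiting fish and contaminate the warm limb of the
realized selection curve.

Dive series sample every 120 s: flat ~4 m nights and irregular 10–80 m days
outside spawning windows, a 650-m V-dive on entry/exit days, and within
windows sinusoidal night oscillations (amplitude 15 m, period 30 min,
depths 5–35 m) with a +2.5 °C internal-temperature rise.  Oil polygons are
irregular (low-order Fourier wobble) blobs around a fixed well whose
locally-projected area follows the growth curve exactly; the default curve
is active 21 Apr – 28 Jul 2010 peaking at 25,000 km², and the default well
sits on the northern edge of the modeled habitat band so the spill borders
spawning habitat as the real one did.

What the generator does *not* emulate: seasonal warming within a year, real
coastlines or currents, behaviourally-mediated dive variation, subsurface
oil, and spatial autocorrelation of geolocation errors.  Passing validation
therefore shows the pipeline recovers structure it is pointed at under
idealized noise — not that the real-data effect sizes would be reproduced.

## Validation experiments and problem sizes

All experiments are scaled-down study conditions chosen once (the tagging
study held 66 fish with 7–193-day Gulf residences; the scaled sizes keep
each experiment in the minutes range on one CPU):

- **CRW fidelity** — 100 CRWs from a 150-step source; pooled resampled step
  lengths vs source (two-sample KS ≈ 0.02), metadata preserved exactly.
- **Null calibration** — 6 zero-preference fish × 60 d per seed across three
  entry years, full six-term model, leave-one-year-out CV; 10-seed mean AUC
  ≈ 0.50 (band 0.40–0.62).
- **Signal recovery** — 12 fish × 180 d under the canonical preference, 6
  CRWs/track, 5-run ensemble; correlation between the ensemble-mean fitted
  SST partial effect and the true quadratic log-preference over 18–30 °C,
  plus 3-fold CV AUC, over 20 seeds.  Measured: median correlation ≈ 0.89
  (per-seed values range 0.63–0.99), CV mean AUC ≈ 0.82.  The correlation is
  structurally capped below ~0.95: wherever presence counts saturate at zero
  (far cold/warm water) the realized usage:availability log-ratio is
  separation-driven and penalty-dependent, and its asymmetry between the
  cold and warm limbs is a property of the data, not the fitter — weaker
  selection symmetrizes the curve (correlation ≈ 0.92) at the cost of
  CV discrimination (≈ 0.75).  The frozen conditions sit at the joint
  optimum of the two properties.
- **Spawning detector** — 6 fish × 60 d, every fish a spawner; trained on
  half the fish, scored on the rest: sensitivity and specificity 1.0 under
  the default signature; the categorical-density model equals a brute-force
  Bayes oracle exactly on an 8-day discrete case.
- **Overlap oracles** — exact clipping vs 100×100 point-in-polygon
  subsampling on random convex polygons (≤ 0.002% area error); conservation
  pct × area = oiled area to rounding; identical/disjoint cases exact;
  cumulative exposure equals an independent double-loop re-summation.
- **Geometry** — 0.25° equatorial cell = 772.77 km²; global 0.25° grid sums
  to 4πR² to < 0.01%; ballistic FPT(100 km) = 2.000 d at 100 km/day.
- **Ensemble stability** — 8 fish × 120 d, 20 runs: the SST term is
  significant in 100% of runs, an added pure-noise covariate in ≈ 5%.
- **Reproducibility** — two end-to-end demo runs under one master seed emit
  byte-identical overlap, scale and fit reports; every random draw flows
  from named substreams of the master seed (SHA-256 of the stream name into
  a `SeedSequence`), with no hidden global state.

## Known limitations

- The per-smooth p-values are Wald-type approximations; their α=0.05
  stability fractions behave correctly under signal and null, but the
  individual p-values should not be read as calibrated.
- The GAM basis (dimension 5, clipped extrapolation beyond the training
  range) cannot express the unbounded tails of the true quadratic
  log-preference outside the sampled covariate range.
- Step-selection usage only approximates the stationary weight exp(s·score);
  transit from release and slow mixing leave realized selection slightly
  steeper and asymmetric relative to truth (see signal recovery above).
- The EEZ mask bundled with the generator is a synthetic stand-in (Gulf
  water north of 25° N), not an authoritative boundary.
- Daily fixes limit FPT/RT resolution to linear interpolation between days;
  radii well below the daily step length are not meaningful.
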