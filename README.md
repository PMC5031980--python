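# bluefinhab

Habitat and spawning-habitat models for Atlantic bluefin tuna (*Thunnus
thynnus*) on their Gulf of Mexico spawning grounds, with oil-spill exposure
accounting.  The package is aimed at movement ecologists and spatial
modellers working with electronic-tag data: it turns presence-only daily
geolocations into presence/pseudo-absence habitat models, detects putative
spawning days from archival dive records, predicts weekly habitat and
spawning surfaces on a 0.25° grid, and intersects them with time-stamped
surface-oil polygons.

Because the underlying tag dataset and damage-assessment oil layers are not
publicly deposited, the package ships a first-class synthetic-data generator
that emulates all of the inputs — tracks biased by a known habitat
preference, dive series with injected nocturnal oscillatory-diving spawning
windows, smooth correlated environmental fields with a warm Loop-Current-like
tongue, and a growing/shrinking oil polygon — so every stage of the analysis
is testable end to end against known ground truth.

## The models

**Pseudo-absences.** Tag tracks record where fish were, never where they
were not.  Each track is paired with correlated random walks (CRWs, 100 per
track): simulated tracks that resample the source track's own empirical
daily step lengths and turning angles, start at its Gulf entry point with
its initial heading, and inherit its dates and per-day geolocation error
radii.  One CRW per track is drawn per model run; refitting over 60 runs
quantifies the error introduced by pseudo-absence choice.

**Habitat GAMM.** Presence (1) versus CRW pseudo-absence (0) is fit with a
logit-link generalized additive mixed model

```
logit P(presence) = β₀ + Σⱼ fⱼ(xⱼ) + b_tag ,   b_tag ~ N(0, σ²)
```

where the fⱼ are penalized cubic regression splines (basis dimension 5,
second-order difference penalty, smoothing parameters by GCV) of
oceanographic covariates — SST and its variability, log chl-a, SSH anomaly
and its variability, log eddy kinetic energy, Ekman pumping, north wind,
bathymetry and rugosity, moon fraction — extracted as error-radius-averaged
means around each daily position.  The per-fish random intercept b_tag is a
ridge-penalized indicator block.  Candidate term sets are ranked by AUC with
AIC as tie-break, and validated by stratified 75/25 k-fold and
leave-one-year-out cross-validation.

**Spawning detector.** Spawning days show shallow oscillatory night diving
with elevated visceral temperature.  Ten daily proxies (night
oscillation-cycle count, median night depth, internal–external temperature
excess at night, day-of-year, moon fraction, …) feed a two-class naive-Bayes
model over per-class kernel-density estimates; each Gulf day gets a
posterior spawning probability.  A parallel spawning/non-spawning GAMM maps
that behaviour onto the environment.

**Exposure.** Weekly habitat and spawning likelihood surfaces are binarized
at ROC thresholds capping the false-positive rate (default 5%), multiplied
into a total-spawning-habitat surface, and intersected with the
nearest-dated oil polygon.  Areas use the exact spherical cell area
R²·Δλ·(sin φ_N − sin φ_S); the report gives the weekly fraction of habitat
oiled, the fraction of the oiled extent that is habitat (whole Gulf and
EEZ-masked), and the cumulative oiled-habitat area.  First-passage-time and
residence-time profiles quantify the spatio-temporal scale of movement.

## Worked example

Run the bundled demo (6 synthetic fish across three entry years, 15 CRWs
per track, 5 ensemble runs, weekly prediction April–August 2010):

```bash
bluefinhab run-all --output-dir demo --seed 7
```

which prints

```
outputs written to demo
cumulative oiled spawning habitat: 51655 km^2
```

and writes `fits.json`, `surfaces.nc`, `overlap.csv`, `scales.csv`,
`spawning_labels.csv` plus the generated inputs under `demo/inputs/`.  For
this seed the full six-term habitat model wins selection (training AUC
0.828; random-splits CV mean AUC 0.789, leave-one-year-out 0.639), the
detector recovers every injected spawning window, and the exposure table
shows oil overlapping 0–8.7% (mean 1.6%) of weekly spawning habitat, summing
to the 51,655 km² cumulative figure above — week-by-week percentages are in
`overlap.csv`.  The movement-scale profile (`scales.csv`) gives a mean
first-passage time of 5.1 days through a 100-km radius, i.e. a fish clears a
100-km cell in under a week, which is why each week is treated as new
habitat.

The same stages are available individually (`simulate`, `occupancy`, `crw`,
`spawn-detect`, `scales`, …); `bluefinhab --help` lists them, and
`configs/demo.yaml` is the demo configuration in file form
(`bluefinhab run-all --config configs/demo.yaml`).

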