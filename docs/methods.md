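# Methods

This note documents the models, conventions and numerical choices behind
`pmexposure`, and what the synthetic-data experiments do and do not
demonstrate.

## Exposure model

Daily personal exposure is a time-weighted average (TWA) over
microenvironments, `C_TWA = Σ Cᵢ·Tᵢ / Σ Tᵢ`. Days are timezone-naive
local calendar days `[00:00, 24:00)`; all coordinates are planar metric
x/y in meters (inputs in longitude/latitude must be projected before
use, since kriging distances and the 500 m grid are metric). The engine
computes every scenario slot-first: concentrations are attached to the
diary's 30-min slots and the generic TWA is applied once per
participant-day over those slices.

Scenario conventions:

* **S1** uses the participant-day mean of the home monitor and of the
  kriged home-cell outdoor series, weighted by fixed handbook times
  (defaults 15.86 h / 3.34 h in `StudyConfig`). It does not use the
  diary.
* **S2** has exactly two terms — home monitor over diary house slots,
  GPS-matched outdoor over diary outdoor slots. Hours in the other four
  labels are excluded from numerator *and* denominator, which is the
  literal reading of the two-term formula; `s2_fold_indoor_into_house`
  folds those hours into the house term instead for sensitivity
  analysis.
* **S3** covers all five indoor labels with model-predicted hourly
  concentrations plus GPS outdoor, weighted by diary hours.
  Transportation is treated as an indoor microenvironment by default (it
  is predicted by the transportation model); `transport_uses_gps=True`
  switches those slots to the GPS outdoor concentration, since a moving
  vehicle is arguably coupled to outdoor air.
* S2/S3 denominators are the day's TAD-accounted hours, which can be
  less than 24 h; no renormalization to 24 h is applied.
* The measured truth is the minute-weighted daily mean of the personal
  monitor; days with fewer than `min_personal_coverage_h` (default 18 h)
  of valid minutes are excluded.
* Diary gaps are explicit: gap slots inherit the previous slot's label,
  and a participant-day with more than `max_diary_gap_h` (default 4 h)
  of gaps is excluded from the TAD-based scenarios (S2, S3) while S1 and
  the measured mean are kept. When the diary label and the GPS position
  disagree, the diary wins; GPS only chooses *where* outdoor
  concentrations are read.

## Ordinary kriging

Sub-hourly sensor readings are averaged to hourly station means and each
hour is kriged independently (the indoor models are hourly, so finer
interpolation would be wasted). Duplicate station coordinates are
averaged before solving. The spherical semivariogram is fitted to the
Matheron empirical variogram on 12 equal-width distance bins up to half
the maximum separation. Bin weights are pair-count/h² (gstat's default),
which concentrates the fit on the short lags that determine kriging
weights; the fit itself is a profiled grid search over the range (for a
fixed range the model is linear in nugget and partial sill, solved by
non-negative least squares) followed by a bounded least-squares polish.
The grid search exists because a joint three-parameter descent reliably
chases large-lag drift of single field realizations. Fitting requires at
least 10 stations with finite values; fewer raises an error telling the
caller to widen the averaging window.

The OK system `[Γ 1; 1ᵀ 0][w; μ] = [γ₀; 1]` is solved once per snapshot
for all cell centers (one factorization, many right-hand sides). With
more than `kriging_max_neighbors` (default 64) stations, each target
uses its nearest stations, and targets sharing a neighbor set share one
solve. Negative predictions are clipped to zero and counted; weight-sum
error is tracked as a diagnostic. Cell membership is half-open with the
lower-left edge inclusive, so every point belongs to exactly one cell;
GPS fixes outside the grid are snapped to the nearest boundary cell and
logged. A fix is matched to the temporally nearest grid hour, ties going
to the earlier one. PM10 is kriged with the same machinery because the
indoor models need the PM2.5/PM10 ratio.

## Indoor microenvironment models

One tree-ensemble regressor per indoor label, trained on six features
(outdoor PM2.5, PM2.5/PM10 ratio, temperature, wind speed, relative
humidity, precipitation) from a model-development table of instrumented
sites; a 20% seeded holdout records R²/RMSE/MAE. Houses use
`ExtraTreesRegressor` (80 trees, `min_samples_leaf=10`), other labels
`XGBRegressor` (200 rounds, depth 5, learning rate 0.1) — the two
algorithms conventionally chosen for these settings — and both are
trained with an **absolute-error (median) objective**. This is a
deliberate choice: indoor series at homes are right-skewed by episodic
minute-scale source events (cooking, smoking) that are statistically
independent of the outdoor/meteorological features, so a
squared-error fit would absorb their mean load into every prediction,
whereas the median objective tracks the infiltration baseline and drops
the episodic mass — exactly the behavior expected of hourly prediction
models that cannot resolve minute-scale transients. Scarce non-house
labels can share one pooled model (`pooled_nonhouse=True`). Training
refuses fewer than 100 aligned hourly rows; predictions are clipped at
zero and forward-filled from hours to the two 30-min slots they cover.

At prediction time the outdoor feature is the participant's GPS-matched
hourly kriged concentration (identical to the home cell while at home),
with the ratio from the jointly kriged PM10 surface clipped into (0, 1].

## Contribution rates

The per-source share on a day is `Cᵢ·Tᵢ/(C_TWA·24)·100` in the
*literal24* convention. Because accounted hours are often below 24, the
literal shares cannot sum to 100 (an S1 day accounts 19.2 h, so they sum
to 80); the *normalized* convention divides by the accounted hours
instead and is the headline output. Both are always computed. CTE and
RME profiles are taken on the day at the 50th / 95th percentile of the
pooled participant-day TWA distribution per scenario (not per
participant), using the nearest-rank order statistic `ceil(p·n)` with
ties broken by earliest date, then participant id — fully deterministic.

## Evaluation

RMSE and MAE follow their standard definitions on matched
participant-days. Pearson r and the CV (100·sd/mean, ddof=1) are
computed on the pooled participant-day series per scenario. The
scenario-to-measured mean ratio is reported to one decimal place.
Paired t-tests compare each scenario with the measured series
(identical series are reported as no-difference with p=1 rather than a
0/0 statistic); one-way ANOVA compares concentration groups across
microenvironments. Undefined quantities (r under zero variance, tests
with < 3 pairs) are reported as missing with a reason, never silently
dropped.

## Synthetic study generator

The panel data the pipeline was designed for are not public, so the
generator emulates their structure. Defaults are the small desk-scale
preset (5 participants × 7 days × 50 sensors on a 10 × 10 km domain);
`PRESETS["study"]` scales to 93 × 60 × 200 with 1-min sensor cadence.

* **Outdoor field**: mean 15 µg/m³; spatial Gaussian random field with
  spherical covariance (range 2000 m, sill 25 (µg/m³)²) drawn on a
  400 m knot lattice and bilinearly interpolated; AR(1) day effects
  (sd 10 µg/m³, ρ 0.5 — winter-city day-to-day variability) and hour
  effects (sd 2, ρ 0.8); diurnal sinusoid (amplitude 3); and an
  urban-core excess of 7 µg/m³ (Gaussian bump, 2 km scale) representing
  traffic/commercial districts. Clipped at zero. The sampler is
  deterministic given a seed.
* **Participants**: suburban homes 3–4.5 km from the core, workplaces
  inside it. Weekday diary template: 12 h house, 6.5 h office, 1 h
  educational, 1 h transportation, 2 h other indoor, 1.5 h outdoor
  (weekends are home-heavy), jittered by ±1 slot. GPS tracks follow the
  template at 1-min cadence with 20 m wander; commutes interpolate
  home↔work; daytime/evening flexible activities sit in the urban core,
  so outdoor exposure along trajectories exceeds the home-cell outdoor
  level — the designed location-based-vs-fixed-grid gap.
* **Indoor concentrations**: static infiltration lines per label
  (house 0.6·outdoor + 5; others 0.4·outdoor + 4 µg/m³) rather than a
  mass-balance ODE — sufficient for the qualitative biases and fully
  parameterizable. Homes additionally receive episodic source events:
  Poisson 3/day, exponential magnitudes (mean 290 µg/m³), exponential
  decay 3/h (≈ 20 min e-folding), i.e. minute-scale transients whose
  mean daily load ≈ 12 µg/m³ raises the home monitor mean to ≈ 26 µg/m³
  over its ≈ 14 µg/m³ baseline.
* **Truth series**: the personal series is the occupied
  microenvironment's concentration minute by minute, with one
  refinement: the stationary home monitor is co-located with the
  episodic sources, so the breathing zone receives only
  `peak_personal_attenuation` (default 0.3) of the recorded peak
  component, and only while at home. Without this monitor/breathing-zone
  decoupling, scenarios that reuse the monitor series (S1/S2) would
  trivially dominate correlation, contradicting the behavior the
  pipeline is designed to exhibit; setting the attenuation to 1 restores
  the strict truth-equals-microenvironment definition (and is used in
  the tests of that identity).
* **Model-development table**: 8 instrumented sites per label over the
  study horizon, with true-field features and infiltration(+peaks for
  houses) targets — emulating the separate campaign such indoor models
  are trained on.

Sensors observe the true field plus N(0, 2²) noise at 10-min cadence in
the small preset (hourly averaging makes the cadence statistically
irrelevant; 1-min in the study preset); monitors add N(0, 1²). PM10 is
PM2.5 divided by a deterministic diurnal ratio (0.52–0.68), floored at
PM2.5. Meteorology is a diurnal temperature cycle with AR(1) weather,
AR(1) wind and humidity, and sparse exponential precipitation.

What the generator does **not** emulate: instrument drift and humidity
artifacts of optical sensors, personal-cloud excess, mass-balance indoor
dynamics, anisotropic or nonstationary outdoor fields, diary
misreporting, GPS dropouts and urban-canyon error. Passing the
directional experiments therefore shows that the pipeline recovers the
designed structure of this data-generating process — not that it would
achieve the same accuracy on real panel data.

## Replicated experiments and problem sizes

The directional experiment runs the full pipeline on 20 seeded
replicates of the small preset (700 participant-days total) and reports
the fraction of replicates in which (i) the daily means order
S2 > S1 > measured > S3, (ii) S3 attains the lowest RMSE and (iii) the
highest Pearson r, and (iv) CTE indoor contributions exceed 80% in all
scenarios. These are majority properties: individual 7-day replicates
are short, day-to-day field variation can be weak in a given week, and
the S2−S1 mean gap (≈ +1 µg/m³ by design) is comparable to its
between-replicate noise, so fractions around 0.6–1.0 per clause are the
expected regime. The unit-test suite uses the same small preset plus a
2-participant tiny preset for speed.

## Numerical and degenerate-case choices

* All randomness flows through `numpy.random.default_rng` seeds carried
  in `SimScenario.rng_seed` / `StudyConfig.rng_seed`; refits and CSV
  round trips are bit-reproducible (CSV floats are written with
  shortest-roundtrip repr and parsed with round-trip precision — tree
  ensembles make downstream results sensitive to 1-ulp input changes).
* Constant observation snapshots yield an effectively zero-sill
  variogram and constant kriged fields; zero-variance series report r as
  missing; zero accounted time raises an undefined-day error; zero TWA
  makes contributions undefined.
* Rejected input rows are logged exactly once each with the first
  violated invariant; structural file problems raise schema errors
  instead.

## Known limitations

* Hourly kriging of a 50-sensor network smooths the urban-core gradient,
  so the home-cell outdoor level inherits part of the core excess; the
  GPS-vs-home outdoor contrast is correspondingly conservative at small
  sensor counts.
* The S1 home/outdoor occupancy times are fixed constants; no
  participant-specific reweighting is attempted.
* Contribution conventions, the transportation switch and the S2
  folding variant are surfaced as configuration rather than resolved,
  since the underlying definitions admit both readings.
* CTE/RME profiles are single-day snapshots by definition and carry no
  uncertainty intervals.
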