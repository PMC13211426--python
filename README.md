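# pmexposure

Personal PM2.5 exposure assessment from an urban sensor network, GPS
tracks and time-activity diaries, via time-weighted-average (TWA)
microenvironment scenarios.

## The problem

Epidemiological studies usually assign PM2.5 exposure from fixed outdoor
monitors, but people spend most of the day indoors and move through
microenvironments with very different concentrations. This package
implements, end to end, a panel-study exposure pipeline for comparing
three increasingly individualized estimators of daily personal exposure
against personal-monitor ground truth:

* **S1** — measured home indoor concentration plus the kriged outdoor
  concentration at the home's grid cell, weighted by fixed
  exposure-factors-handbook occupancy times (15.86 h at home, 3.34 h
  outdoors);
* **S2** — the same measured home concentration, but GPS-matched outdoor
  concentrations and the participant's own diary (TAD) hours;
* **S3** — model-predicted indoor concentrations for every occupied
  microenvironment (house, office, educational facility, transportation,
  other indoor) plus GPS-matched outdoor concentrations, weighted by
  diary hours.

All three are instances of the generic time-weighted average

    C_TWA = Σᵢ Cᵢ·Tᵢ / Σᵢ Tᵢ        [µg/m³]

where Cᵢ is the concentration of microenvironment *i* and Tᵢ the hours
spent there. Supporting machinery:

* **Ordinary kriging** of ~hourly sensor-network station means onto a
  regular 500 m grid (spherical semivariogram, weighted-least-squares
  fit, OK weights constrained to sum to one);
* **trajectory fusion** of 1-min GPS fixes, 30-min diaries and the
  kriged surfaces into per-slot occupancy/concentration series;
* **indoor prediction models** per microenvironment (extremely
  randomized trees for houses, gradient-boosted trees elsewhere) from
  six inputs: outdoor PM2.5, the PM2.5/PM10 ratio, temperature, wind,
  relative humidity and precipitation;
* **contribution rates** Cᵢ·Tᵢ / (C_TWA · 24) · 100 (plus a normalized
  variant dividing by the accounted hours) summarized at the days of the
  50th (CTE) and 95th (RME) percentile of the daily TWA distribution;
* **evaluation**: RMSE, MAE, Pearson r, CV, paired t-tests and ANOVA;
* a **synthetic study generator** that emulates the panel data (the real
  data are restricted): a spatiotemporal outdoor field with an
  urban-core excess, infiltration-driven indoor series with episodic
  cooking-like source events at home, diaries, GPS commutes and a
  breathing-zone truth series.

## Worked example

```python
from pmexposure import (SimScenario, StudyConfig, ExposureData,
                        TWAExposureModel, simulate_study)

study = simulate_study(SimScenario(rng_seed=1))        # 5 participants x 7 days
data = ExposureData.from_simulation(study)
results = TWAExposureModel(data, StudyConfig(rng_seed=1)).fit()
print(results.summary())
```

prints

```
Daily TWA PM2.5 by scenario (ug/m3)
------------------------------------------------------------------------------
scenario  n_days     mean       sd   cv_pct   median      max      mae     rmse  pearson_r  mean_ratio_to_measured
measured      35    12.22     3.22    26.32    11.28    21.71      NaN      NaN        NaN                    1.00
      s1      35    18.21     7.54    41.42    16.58    43.52     6.00     8.40       0.65                    1.50
      s2      35    19.26     9.22    47.87    17.35    52.01     7.16     9.95       0.75                    1.60
      s3      35    10.93     2.75    25.14     9.88    15.71     1.44     2.09       0.86                    0.90

Indoor/outdoor contribution (normalized)
------------------------------------------------------------------------------
scenario level  indoor_pct  outdoor_pct
      s1   CTE        90.9          9.1
      s1   RME        90.7          9.3
      s2   CTE        93.3          6.7
      s2   RME        97.6          2.4
      s3   CTE        92.9          7.1
      s3   RME        90.7          9.3
```

Reading the table: S1 and S2 overestimate the measured daily exposure
(ratios 1.5 and 1.6) because they extend the stationary home monitor —
which sits next to episodic indoor sources — over most of the day, and
S2 is highest because it also uses the elevated urban outdoor
concentrations along the participant's movement path. S3, built from
hourly indoor *predictions*, misses the short-term source peaks and
slightly underestimates (ratio 0.9) but tracks day-to-day variation best
(lowest RMSE/MAE, highest r). Indoor microenvironments dominate the
exposure budget (≈ 90% at both CTE and RME levels) in every scenario.

The same pipeline is available from the shell:

```bash
exposure simulate --preset small --seed 7 --out data/
exposure krige    --sensors data/sensors.csv --out grid/
exposure estimate --data data/ --out est/ --seed 7
exposure evaluate --daily est/daily_exposure.csv --out eval/
```

With a fixed seed the whole chain is byte-reproducible. `exposure
validate <file> --kind sensor|diary|track|met|series` checks any input
table and reports rejected rows.

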