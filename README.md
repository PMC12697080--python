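# heatkit

Station-scale heatwave climatology and health-impact pipeline:

- **synthetic** — seeded generators for reference ("pseudo-reanalysis") and
  model ("pseudo-GCM") daily Tmax/Tmin series (seasonal cycle + warming trend
  + AR(1) noise + injected multi-day warm episodes), station catalogues over a
  bounding box, and country-year demography tables. Ground-truth parameters
  (true bias, trend, episode dates) ride along in `attrs` for recovery tests.
- **indices** — calendar-day percentile climatologies (15-day window, type-7
  estimator) and yearly indices: TX90p, TN90p, heatwave number/frequency/
  duration (HWN/HWF/HWD), magnitude (HWM, mean Tmax over the year's heatwave
  days) and amplitude (HWA, hottest event day). Heatwaves are maximal runs of
  ≥ 3 consecutive days with Tmax strictly above the calendar-day 90th
  percentile; runs crossing Dec-31 keep their duration and count in the start
  year.
- **bias** — per-calendar-month mean–variance correction
  `x̂ = μ_o + (σ_o/σ_m)(x − μ_m)`, bias/RMSE evaluation, and equal-weight
  ("one model, one vote") ensembling of corrected members.
- **trends** — Mann–Kendall test (tie-corrected variance, continuity
  correction, two-sided normal p) with Sen's slope.
- **severity** — HWM severity categories with regional coverage quotas, and
  heatwave-attributable all-cause mortality
  `days × deaths/day × (RR−1)/RR` with RR-CI propagation
  (default RR 1.20, 95% CI 1.02–1.41).
- **spatial** — inverse-distance-weighted interpolation (k = 4 nearest
  stations, power 2) onto a regular lon/lat grid, and 2nd/98th-percentile
  display clipping (± max-|.| for signed fields).
- **pipeline / cli** — end-to-end orchestration with a JSON manifest
  (config hash + sha256 per product); byte-reproducible under a fixed seed.

## CLI

```sh
# full pipeline (synthetic generation → thresholds → indices → bias
# correction + ensembling → trends → severity + burden → rasters → manifest)
heatkit --config config.yaml run-all --out out/

# individual stages (recomputed from the seed; only stage products written)
heatkit --config config.yaml generate  --out out/
heatkit --config config.yaml indices   --out out/
heatkit --config config.yaml correct   --out out/
heatkit --config config.yaml trends    --out out/
heatkit --config config.yaml burden    --out out/
heatkit --config config.yaml rasterize --out out/
```

Minimal config (the seed is mandatory):

```yaml
synthetic:
  seed: 1
  n_stations: 20
  start_year: 1962
  end_year: 2021
periods:
  historical: [1962, 2021]
  near: [2022, 2051]
  far: [2071, 2100]
scenarios:
  SSP2-4.5: 0.04
  SSP5-8.5: 0.08
models:
  - {name: GCM-A, bias: 2.5, var_inflation: 1.4}
  - {name: GCM-B, bias: -1.5, var_inflation: 0.8}
```

Without `--config`, the built-in demo configuration above is used;
`--seed` overrides the config seed.

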