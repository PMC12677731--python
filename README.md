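# dailygait

Free-living gait analysis from a lower-back triaxial accelerometer, plus the
cohort statistics used to relate gait metrics to age and physical function:

1. **recording_io** — CSV recording I/O (with JSON sidecar metadata),
   resampling (e.g. 50 → 100 Hz), temperature-based wear detection, and
   valid-day classification (≥ 18 h wear).
2. **gait_events** — initial-contact detection on the vertical axis
   (detrend → low-pass → integrate → Mexican-hat wavelet smoothing →
   positive peaks between zero-crossings) and step-peak detection on the
   acceleration norm (3.2 Hz FIR + adaptive amplitude / peak-to-peak
   thresholds).
3. **bouts** — walking-bout assembly (≥ 2 steps, gap ≤ 1.5 s + running mean
   step duration) and per-bout duration, cadence, inverted-pendulum step
   length `K·2·√(2lh − h²)`, speed and distance.
4. **aggregate** — per-subject outcomes: mean daily steps over valid days,
   habitual (histogram-mode) and fast (95th-percentile) cadence/speed,
   maximum bout distance, and the four bout-duration categories
   (≤10 s, >10–30 s, >30–60 s, >60 s).
5. **cohort** — age/SPPB stratification, descriptives, Mann-Whitney U and
   χ² tests.
6. **powerlaw_gamma** — gamma regression with log link,
   `y = exp(β0 + β1·xᵝᵖ)·ε` with unit-mean gamma error, the exponent
   profiled by maximum likelihood and kept only when AIC improves over
   βp = 1; percent-change predictions; singleton-age exclusion.
7. **synthetic** — simulator for recordings (with exact ground-truth gait
   events), multi-day "weeks", and cohort tables drawn from the gamma model.
8. **cli** — end-to-end orchestration with validated JSON config.

## CLI

```sh
# synthetic multi-day recording + ground truth (and optional cohort table)
dailygait simulate --out data/ --seed 1 [--week-config week.json] [--cohort]

# recordings -> bouts.csv, days.csv, wear.csv, subject_summary.csv
dailygait process --in data/recording.csv --config config.json --out out/

# recompute subject summaries from tables
dailygait aggregate --bouts out/bouts.csv --days out/days.csv --out out/

# descriptives + sex comparisons (Mann-Whitney, chi-square)
dailygait stats --cohort cohort.csv --out out/

# gamma regression per sex for one metric and covariate
dailygait fit --cohort cohort.csv --metric mean_daily_steps --covariate age --out out/

# box plot of a metric by age band and sex
dailygait report --cohort cohort.csv --metric mean_daily_steps --out out/
```

Configuration is a JSON file validated against `dailygait.cli.RunConfig`
(unknown keys rejected); every run writes `manifest.json` with the config
hash, seed and package version so outputs are exactly reproducible.

### Recording format

`t,acc_v,acc_ap,acc_ml[,temp]` CSV (time in seconds from start,
acceleration in g, temperature in °C) plus a sidecar `<name>.json` with
`subject_id`, `start_time` (ISO-8601), nominal `rate` and optional
`temp_rate`.

### Output columns

- `bouts.csv`: subject_id, day, start_s, duration_s, n_steps, cadence_spm,
  mean_step_length_m, speed_mps, distance_m
- `days.csv`: subject_id, day_index, date, wear_hours, is_valid
- `wear.csv`: subject_id, start_s, end_s, worn
- `subject_summary.csv`: mean_daily_steps, fast/habitual cadence and speed,
  max_bout_distance, duration-category proportions (`prop_*`) and minutes
  (`min_*`), n_valid_days, n_bouts

## Notes

- Days are local midnight-to-midnight; `day_seconds` can shrink the day
  length for desk-scale synthetic data (the 18/24 validity fraction scales
  accordingly).
- Daily step totals count each initial contact as one step; set
  `aggregation.steps_per_bout = "n_intervals"` to count intervals instead.
- Weekly (distribution-based) metrics pool all bouts regardless of day
  validity; `aggregation.weekly_valid_days_only` restricts them.
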