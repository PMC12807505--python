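# File formats

All formats are plain delimited text with a header row. Paths in a
manifest are resolved relative to the manifest file.

## Pressure trace (`traces/<animal_id>.csv`)

| column         | type  | units | notes                                   |
|----------------|-------|-------|-----------------------------------------|
| `timestamp_s`  | float | s     | seconds since lights-on (ZT0), strictly increasing |
| `pressure_mmHg`| float | mmHg  | finite                                  |

Any sampling rate ≥ 1 Hz is accepted; analysis resamples to 1 Hz.

## Delivery events (`events.csv`)

| column         | type   | units  | notes                              |
|----------------|--------|--------|------------------------------------|
| `animal_id`    | string |        |                                    |
| `group`        | string |        | treatment label                    |
| `event_type`   | string |        | currently always `pup_delivery`    |
| `timestamp_min`| int    | min    | ZT-referenced whole minutes        |

## Cohort manifest (`manifest.csv`)

| column        | type   | notes                                        |
|---------------|--------|----------------------------------------------|
| `animal_id`   | string | unique                                       |
| `group`       | string |                                              |
| `d_drg`       | 0/1    | PIEZO1/2 deleted in DRG sensory neurons      |
| `d_uterus`    | 0/1    | PIEZO1/2 deleted in the uterus               |
| `trace_path`  | path   | relative to the manifest                     |
| `events_path` | path   | relative to the manifest                     |

## Patch-clamp sweep (`<sweep>.csv` + `<sweep>.json`)

CSV columns `time_ms` (uniform ascending grid) and `current_pA`; the JSON
sidecar carries `stimulus_onset_ms`, `hold_duration_ms`, `depth_um`,
`sample_rate_hz` and `ramp_speed_um_per_ms`.

## Outputs

* `summaries.csv` — one row per animal: `animal_id, group, d_drg,
  d_uterus, mean_peak_pressure, n_peaks, mean_interpup_interval,
  onset_zt, onset_after_zt3` (undefined statistics are empty cells).
* `peaks/<animal_id>.csv` — `time_s, height_mmHg, prominence_mmHg` for
  the analysis window.
* `stats_report.csv` — `test, outcome, statistic, p_value, n`.
* `gls_report.csv` — coefficient table (estimate, SE, t, one-sided p,
  df), group variances, convergence log.
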