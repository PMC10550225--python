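# divetag

Analysis pipeline for archival-tag records from diving pelagic predators:
dive extraction and U/V classification, tag-light attenuation profiling with
deep scattering-layer overlap detection, per-dive bioenergetics with
hypothetical-dive comparisons, biome-level statistics, and diel backscatter
composites — plus a synthetic-data generator with known ground truth that
makes every stage testable without real tags.

## Modules

| module | what it does |
| --- | --- |
| `divetag.synthetic` | Ocean scenarios (two-layer temperature, attenuation field with DCM and migrating scattering layers), tag-record and backscatter simulation |
| `divetag.dives` | Mixed-layer-depth estimation, dive extraction at MLD + 10 m, 75%-of-max phase segmentation, daytime/DCM-cutoff filtering, U/V classification, per-dive metrics |
| `divetag.light` | Midday (solar noon ± 1 h) attenuation profiles from depth-light series, QC, detection of attenuation increases below the chlorophyll cutoff, within-biome profile clustering |
| `divetag.energetics` | Parametric metabolic-rate model MR(speed, temp), per-dive cost / cost rate / profitability, hypothetical deeper dives and cost-equivalent bottom durations |
| `divetag.biomes` | Province box assignment, biome summaries and percent changes, cost-rate-vs-minimum-temperature power fits, inverse-distance-weighted fields |
| `divetag.acoustics` | Hour-of-day x depth backscatter composites, layer centroid/peak traces, dive-depth quartile overlays |
| `divetag.solar` | NOAA sunrise / solar-noon / sunset equations |

## Command line

```bash
# simulate a tag record from YAML configs (see tests/test_cli.py for schema)
divetag simulate --scenario scenario.yaml --behavior behavior.yaml \
    --out sim/ --seed 1

# dive extraction, filtering, classification, metrics
divetag dives --series sim/series.csv --positions sim/positions.csv \
    --dcm-table dcm.yaml --out dives/

# midday attenuation profiles + scattering-layer overlap detection
divetag light --series sim/series.csv --positions sim/positions.csv \
    --dcm-table dcm.yaml --out light/

# per-dive metabolic cost, cost rate, profitability
divetag energetics --series sim/series.csv --positions sim/positions.csv \
    --out energetics/

# biome summaries + power fit
divetag stats --dives dives/dives.csv --energetics energetics/energetics.csv \
    --positions sim/positions.csv --out stats/

# diel backscatter composite
divetag acoustics --backscatter sim/backscatter.csv --out acoustics/
```

Tag series are CSV (`timestamp,depth_m,temp_c,light`, ISO-8601 UTC), daily
positions are `date,lat,lon`, and backscatter is long-format
`hour,depth_m,sv_db`. The `light` channel is ln-irradiance by default; pass
`--light-channel linear` for linear-scale sensors.

## Notes

- The metabolic-rate model is a calibrated parametric surrogate
  `MR = (R0 + c*U^p) * exp(beta * max(0, T_ref - T))` with cold-elevated
  metabolism, not a digitized experimental response surface; all parameters
  are configurable (`divetag.energetics.MetabolicModel`).
- The packaged DCM cutoff table (`divetag.dives.DEFAULT_DCM_TABLE`) contains
  editable placeholder values per 10-degree latitude band.
- Scattering-layer detection is presence-only: `overlap=False` means "no
  detection", and profiles failing preconditions return a distinct
  not-evaluated result.
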