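# landcarbon

A desk-scale, spatially explicit forest carbon simulator using the
"gain–loss" (stock-flow) method: a 14-pool per-cell carbon engine (5 live
pools, 9 dead-organic-matter pools) driven by species growth curves,
climate-derived growth and decay multipliers, a long-run fire-regime
spin-up, and a raster state-and-transition model of land-use change and
disturbance. Annual accounting reports NPP, heterotrophic respiration,
NEP, NBP, combustion emissions and harvest export, with strict
conservation checks every timestep.

## Layout

| module | role |
|---|---|
| `landcarbon.params` | species parameters, Von Bertalanffy volume curves, volume→biomass expansion, NPP schedules and allocation proportions |
| `landcarbon.engine` | the annual 8-step base-flow state machine and transition-triggered disturbance matrices |
| `landcarbon.climate` | precipitation/temperature NPP functions, anomaly growth multipliers, Q10 decay multipliers |
| `landcarbon.spinup` | 3000-year fire-regime DOM spin-up, fire/clearcut stock-by-age tables, initial landscape stocks |
| `landcarbon.stsm` | state classes, transition scheduling (probability / target area / event rasters), fire severity, post-fire recovery, bootstrap rates, reforestation |
| `landcarbon.driver` | scenario orchestration, sensitivity toggles (climate on/off, LULC-disturbance on/off), annual accounts |
| `landcarbon.fixtures` | seed-controlled synthetic landscapes, climate series and disturbance events |
| `landcarbon.io` / `landcarbon.rasters` / `landcarbon.cli` | CSV/YAML/JSON/TIFF formats, validation, run manifest, CLI |

Packaged defaults live in `src/landcarbon/data/`: the 28-row species
parameter table plus documented default expansion factors, base flow
rates, turnover routing and disturbance matrices (the latter four are
plausible defaults intended for testing — override them for science use).

## CLI

```bash
# write a ready-to-run synthetic scenario (rasters + YAML)
landcarbon fixtures --outdir demo --seed 1 --size 100 --years 20

# spin up all species and export state attribute tables
landcarbon spinup --out tables.csv

# initial per-pool stock rasters from maps + tables
landcarbon init --scenario demo/scenario.yaml --tables tables.csv --out stocks.tif

# run the scenario (accounts.csv, NBP raster, manifest.json)
landcarbon simulate --config demo/scenario.yaml --outdir demo/out

# single-stand verification: re-run the engine against the stored table
landcarbon verify --species "Forest: Douglas-fir Group"
```

## Conventions

- Pool state is `(cells, 14)` float arrays ordered as
  `landcarbon.pools.ALL_POOLS`; units are tons C/ha.
- All stochastic operations take an explicit `numpy.random.Generator` or
  seed; identical seeds give bitwise-identical outputs.
- Rasters are row-major TIFFs (cell (0,0) top-left) with georeferencing
  carried as JSON in the image description tag; areas always come from a
  configured `cell_area_ha` (default 100 ha, i.e. 1-km cells).
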