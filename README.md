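# thermosalmon

Coupled modeling of river thermal habitat and juvenile Pacific salmon
growth: a process-based 1-D water-temperature model (solar/riparian shading,
surface and streambed heat fluxes, steady low-flow routing) driving a
Wisconsin-type bioenergetics model, under a grid of riparian-vegetation and
future-climate scenarios.

## What's inside

| module | role |
| --- | --- |
| `thermosalmon.synth` | seeded synthetic rivers, meteorology, landcover, tributaries, and known-truth "observation twins" |
| `thermosalmon.solar` | solar position, clear-sky radiation, cloudiness inversion from measured radiation, transect landcover sampling, per-timestep effective shade |
| `thermosalmon.hydraulics` | tributary accrual as fixed flow fractions, Manning depth/velocity (rectangular channel), junction temperature mixing |
| `thermosalmon.heat` | surface/bed flux assembly, explicit upwind advection at a 2-minute step with a 5-day flush, two-stage 8-candidate calibration |
| `thermosalmon.scenarios` | vegetation treatments (current / removal / ≥24.4 m buffer growth) and delta + diurnal-disaggregation climate forcing (25-scenario grid) |
| `thermosalmon.bioenergetics` | daily energy balance (consumption − metabolism − waste), species parameter registry, per-node batch growth, zero-growth temperature solver |
| `thermosalmon.metrics` | bias/RMSE/NSE fit, 7DADM, life-stage threshold exceedance, two-way scenario ANOVA, comparison reports |
| `thermosalmon.pipeline` / `cli` | synth → calibrate → temperature scenarios → growth → report orchestration with a run manifest |

Species parameter files live in `src/thermosalmon/species/*.yaml` with
per-value provenance comments; they are data, not code.

## CLI

```bash
thermosalmon synth --seed 1 --out runs/inputs          # synthetic dataset
thermosalmon all --config run.yaml                     # full pipeline
thermosalmon calibrate --config run.yaml               # twin calibration
thermosalmon scenario run --config run.yaml            # scenario grid
thermosalmon growth --config run.yaml                  # growth from temps
thermosalmon report --config run.yaml                  # comparison reports
```

`run.yaml` keys (all optional): `seed`, `out_dir`, `n_nodes`, `start_date`,
`end_date`, `flush_days`, `dt_seconds`, `species`, `p_cmax`, `start_mass`,
`ed_pred`, `ed_prey`, `substrate`, `physical_sediment`, `run_calibration`,
`scenario_list` (`grid` or a list of
`{climate_period, rcp, vegetation}` mappings), `synth_overrides`.
Exit codes: 0 success, 2 validation error, 3 numerical failure.

## Notes on fidelity

- The sediment thermal diffusivity/conductivity input pair is kept verbatim
  from the source table (the printed values appear transposed);
  `SubstrateParams.physical_sediment()` swaps them into the physically
  plausible orientation and is the default for synthetic-twin work.
- The temperature model is a faithful re-implementation of the documented
  model structure, not a bit-compatible port of any specific solver release;
  it is validated by conservation/convergence/monotonicity properties and
  parameter-recovery on synthetic twins.
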