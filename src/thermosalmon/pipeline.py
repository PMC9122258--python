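"""End-to-end orchestration: synth -> calibrate -> temperature scenarios ->
growth -> reports, with a manifest recording seed, config hash and timings.

Every stage writes its artifacts to the output directory so each stage is
independently inspectable and re-runnable; all randomness funnels through
the single seed in RunConfig.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, bioenergetics, heat, io, metrics, scenarios, solar, synth


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "runs/default"
    n_nodes: int = 82
    start_date: str = "2019-06-10"
    end_date: str = "2019-09-18"
    flush_days: int = 5
    dt_seconds: float = 120.0
    species: str = "chinook"
    p_cmax: float = 0.5
    start_mass: float = 5.0
    ed_pred: float = 4.7
    ed_prey: float = 3.0
    substrate: dict = dc_field(default_factory=dict)  # SubstrateParams overrides
    physical_sediment: bool = True
    run_calibration: bool = False
    scenario_list: object = "grid"  # "grid" or list of dicts
    log_level: str = "INFO"
    synth_overrides: dict = dc_field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.read_yaml(path) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def substrate_params(self) -> heat.SubstrateParams:
        base = (
            heat.SubstrateParams.physical_sediment
            if self.physical_sediment
            else heat.SubstrateParams
        )
        return base(**self.substrate)

    def synthetic_config(self) -> synth.SyntheticConfig:
        return synth.SyntheticConfig(
            seed=self.seed,
            n_nodes=self.n_nodes,
            start_date=self.start_date,
            end_date=self.end_date,
            flush_days=self.flush_days,
            **self.synth_overrides,
        )

    def bioe_inputs(self) -> bioenergetics.BioeInputs:
        return bioenergetics.BioeInputs(
            start_mass=self.start_mass, p_cmax=self.p_cmax,
            ed_pred=self.ed_pred, ed_prey=self.ed_prey,
        )

    def scenario_specs(self) -> list:
        if self.scenario_list == "grid":
            return scenarios.scenario_grid()
        return [scenarios.ScenarioSpec(**d) for d in self.scenario_list]


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}, sort_keys=True, default=str
    ).encode()
    return hashlib.sha256(payload).hexdigest()


def _model_config(cfg: RunConfig, scfg: synth.SyntheticConfig) -> heat.ModelConfig:
    return heat.ModelConfig(
        latitude=scfg.latitude,
        longitude=scfg.longitude,
        utc_offset=scfg.utc_offset,
        station_elevation_m=scfg.station_elevation_m,
        dt_seconds=cfg.dt_seconds,
        flush_days=cfg.flush_days,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "temps").mkdir(exist_ok=True)
    (out / "growth").mkdir(exist_ok=True)
    (out / "report").mkdir(exist_ok=True)
    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "stages": {},
        "outputs": [],
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3),
                    "ok": exc_type is None,
                }
                if exc_type is not None:
                    manifest["stages"][name]["error"] = f"{exc_type.__name__}: {exc}"
                    io.write_json(manifest, out / "manifest.json")
                return False

        return _Timer()

    scfg = cfg.synthetic_config()
    mcfg = _model_config(cfg, scfg)
    substrate = cfg.substrate_params()

    with stage("synth"):
        dataset = synth.make_dataset(scfg)
        io.write_reach(dataset.reach, out / "inputs" / "reach.csv")
        io.write_landcover(dataset.landcover, out / "inputs" / "landcover.csv")
        io.write_met(dataset.met, out / "inputs" / "met.csv", scfg.utc_offset)
        io.write_boundary(dataset.boundary, out / "inputs" / "boundary.csv", scfg.utc_offset)
        io.write_tributaries(dataset.tributaries, out / "inputs", scfg.utc_offset)

    if cfg.run_calibration:
        with stage("calibrate"):
            obs, truth = synth.make_observation_twin(substrate, scfg, dataset=dataset)
            result = heat.calibrate(
                heat.default_candidates(substrate),
                obs,
                lambda cand: synth.run_truth(dataset, cand),
            )
            substrate = result.selected
            io.write_json(result.fit_report, out / "report" / "fit_report.json")

    # cloudiness depends only on observed radiation: invert once, reuse
    with stage("cloudiness"):
        hours = scfg.hourly_index()
        em = np.array(
            [
                solar.clear_sky_radiation(
                    solar.solar_position(scfg.latitude, scfg.longitude, ts, scfg.utc_offset),
                    scfg.station_elevation_m,
                    ts.dayofyear,
                )
                for ts in hours
            ]
        )
        cloud = pd.Series(
            solar.cloudiness_series(
                dataset.met["solar_wm2"].to_numpy(), np.where(em > 1.0, em, 0.0)
            ),
            index=hours,
        )

    specs = cfg.scenario_specs()
    shade_cache = {}
    outputs = {}
    with stage("scenarios"):
        for spec in specs:
            bundle = scenarios.build_scenario(
                spec, dataset.landcover, dataset.met, dataset.boundary, delta_seed=cfg.seed
            )
            veg = spec.vegetation
            if veg not in shade_cache:
                shade_cache[veg] = solar.build_shade_series(
                    dataset.reach, bundle.landcover, hours,
                    scfg.latitude, scfg.longitude, scfg.utc_offset,
                )
            shade, vts = shade_cache[veg]
            field = heat.run_model(
                dataset.reach, bundle.met, bundle.boundary, dataset.tributaries,
                shade, substrate, scfg.dates, config=mcfg, view_to_sky=vts,
                cloudiness=cloud,
            )
            outputs[spec.name] = {"field": field.data, "spec": spec, "provenance": bundle.provenance}
            io.write_temps(field, out / "temps" / f"{spec.name}.csv", scfg.utc_offset)
            io.write_yaml(bundle.provenance, out / "temps" / f"{spec.name}.provenance.yaml")

    with stage("growth"):
        params = bioenergetics.load_species(cfg.species)
        inputs = cfg.bioe_inputs()
        for name, entry in outputs.items():
            trajectories, summary = bioenergetics.batch_growth(entry["field"], inputs, params)
            entry["growth_summary"] = summary
            entry["trajectories"] = trajectories
            io.write_growth(trajectories, out / "growth" / f"{name}.csv")
        io.write_json(
            {name: entry["growth_summary"] for name, entry in outputs.items()},
            out / "growth" / "growth_summary.json",
        )

    with stage("report"):
        current_name = scenarios.ScenarioSpec().name
        report = metrics.scenario_report(
            {n: {"field": e["field"], "growth_summary": e["growth_summary"]}
             for n, e in outputs.items()},
            current_key=current_name,
        )
        io.write_json(report, out / "report" / "scenario_report.json")

        seven_rows = []
        for name, entry in outputs.items():
            table = metrics.sevendadm_table(entry["field"])
            for col in table.columns:
                for date, val in table[col].items():
                    seven_rows.append(
                        {"scenario": name, "node_id": col,
                         "date": pd.Timestamp(date).date().isoformat(), "value_c": val}
                    )
        pd.DataFrame(seven_rows).to_csv(out / "report" / "sevendadm.csv", index=False)

        exc_rows = []
        for name, entry in outputs.items():
            table = metrics.exceedance_table(entry["field"])
            table.insert(0, "scenario", name)
            exc_rows.append(table)
        pd.concat(exc_rows).to_csv(out / "report" / "exceedance.csv", index=False)

        # factorial ANOVA over the climate x vegetation grid (node replicates)
        anova_rows = []
        for name, entry in outputs.items():
            spec = entry["spec"]
            for traj in entry["trajectories"]:
                anova_rows.append(
                    {"climate": f"{spec.climate_period}_{spec.rcp}",
                     "vegetation": spec.vegetation, "change_g": traj.final_change}
                )
        frame = pd.DataFrame(anova_rows)
        future = frame[frame["climate"] != "current_none"]
        if len(future["climate"].unique()) >= 2 and len(future["vegetation"].unique()) >= 2:
            io.write_json(metrics.scenario_growth_anova(future), out / "report" / "anova.json")

    io.write_json(manifest, out / "manifest.json")
    return manifest
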