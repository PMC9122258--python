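"""Scenario grid: riparian vegetation treatments x future climate forcing.

Vegetation treatments act on the wide landcover transect table; climate
scenarios shift hourly air temperature by the delta + diurnal-disaggregation
method (future hour = projected daily mean + observed within-day anomaly).
The upstream boundary water temperature is held constant across climate
scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar

CLIMATE_PERIODS = ("current", "2020", "2040", "2060", "2080")
RCPS = ("none", "4.5", "8.5")
VEGETATION_MODES = ("increase", "current", "loss")

DEFAULT_BUFFER_WIDTH_M = 100.0
DEFAULT_MIN_HEIGHT_M = 24.4

#: Mean warming (degC) per (period, rcp): printed 2080 means, earlier
#: periods interpolated linearly toward zero at the current period.
DEFAULT_WARMING = {
    ("2020", "4.5"): 2.11 * 0.25, ("2020", "8.5"): 3.48 * 0.25,
    ("2040", "4.5"): 2.11 * 0.50, ("2040", "8.5"): 3.48 * 0.50,
    ("2060", "4.5"): 2.11 * 0.75, ("2060", "8.5"): 3.48 * 0.75,
    ("2080", "4.5"): 2.11, ("2080", "8.5"): 3.48,
}
DEFAULT_WARMING_SD = {"4.5": 0.63, "8.5": 0.59}


@dataclass(frozen=True)
class ScenarioSpec:
    climate_period: str = "current"
    rcp: str = "none"
    vegetation: str = "current"

    def __post_init__(self):
        if self.climate_period not in CLIMATE_PERIODS:
            raise ValueError(f"unknown climate period {self.climate_period!r}")
        if self.rcp not in RCPS:
            raise ValueError(f"unknown RCP {self.rcp!r}")
        if self.vegetation not in VEGETATION_MODES:
            raise ValueError(f"unknown vegetation mode {self.vegetation!r}")
        if (self.rcp == "none") != (self.climate_period == "current"):
            raise ValueError("rcp must be 'none' exactly when climate_period is 'current'")

    @property
    def name(self) -> str:
        return f"{self.climate_period}_{self.rcp}_{self.vegetation}".replace(".", "")


def scenario_grid() -> list:
    """The canonical 25-scenario grid: 1 baseline + 4 periods x 2 RCPs x 3
    vegetation treatments."""
    grid = [ScenarioSpec()]
    for period in CLIMATE_PERIODS[1:]:
        for rcp in ("4.5", "8.5"):
            for veg in VEGETATION_MODES:
                grid.append(ScenarioSpec(period, rcp, veg))
    return grid


@dataclass
class ClimateDelta:
    """Projected daily mean air temperature (degC), one value per sim day."""

    daily_mean: pd.Series  # index: dates (day resolution)
    period: str = ""
    rcp: str = ""

    def covers(self, days: pd.DatetimeIndex) -> bool:
        return days.isin(self.daily_mean.index).all()


def synthetic_delta(
    met: pd.DataFrame,
    period: str,
    rcp: str,
    seed: int = 0,
    warming: dict = None,
    warming_sd: dict = None,
) -> ClimateDelta:
    """Projected daily means: observed daily means + offset + day-to-day noise.

    Stands in for a downscaled-GCM archive; offsets default to the printed
    2080 means (+2.11 RCP 4.5, +3.48 RCP 8.5, SD 0.63/0.59) with earlier
    periods scaled linearly.
    """
    warming = warming or DEFAULT_WARMING
    warming_sd = warming_sd or DEFAULT_WARMING_SD
    key = (period, rcp)
    if key not in warming:
        raise ValueError(f"no warming offset for {key}")
    obs_daily = met["air_c"].groupby(met.index.floor("D")).mean()
    rng = np.random.default_rng([seed, hash(key) % (2**31)])
    noise = rng.normal(0.0, warming_sd[rcp], len(obs_daily))
    return ClimateDelta(
        daily_mean=obs_daily + warming[key] + noise, period=period, rcp=rcp
    )


def modify_vegetation(
    landcover: pd.DataFrame,
    mode: str,
    buffer_width_m: float = DEFAULT_BUFFER_WIDTH_M,
    min_height_m: float = DEFAULT_MIN_HEIGHT_M,
) -> pd.DataFrame:
    """Apply a vegetation treatment to the wide landcover table.

    loss: all transect heights to zero over the whole reach, both banks.
    increase: within ``buffer_width_m`` of the bank (transect samples at
    distance <= buffer), heights below ``min_height_m`` are raised to it;
    taller vegetation keeps its height. current: identity.
    """
    if mode not in VEGETATION_MODES:
        raise ValueError(f"unknown vegetation mode {mode!r}")
    out = landcover.copy()
    if mode == "current":
        return out
    height_cols = [c for c in out.columns if c.endswith("_height_m")]
    if mode == "loss":
        out[height_cols] = 0.0
        return out
    for col in height_cols:
        sample = int(col.split("_s")[1].split("_")[0])
        dist = sample * solar.SAMPLE_SPACING_M
        if dist <= buffer_width_m:
            out[col] = np.maximum(out[col], min_height_m)
    return out


def climate_adjust(hourly_met: pd.DataFrame, delta: ClimateDelta) -> pd.DataFrame:
    """Future hourly meteorology via delta + diurnal disaggregation.

    future(d, h) = projected_daily_mean(d) + (observed(d, h) -
    observed_daily_mean(d)). Only air temperature changes; humidity, wind
    and radiation pass through.
    """
    days = hourly_met.index.floor("D")
    if not days.unique().isin(delta.daily_mean.index).all():
        missing = days.unique().difference(delta.daily_mean.index)
        raise ValueError(f"climate delta missing {len(missing)} day(s), first {missing[0]}")
    obs_daily = hourly_met["air_c"].groupby(days).transform("mean")
    proj = delta.daily_mean.reindex(days).to_numpy()
    out = hourly_met.copy()
    out["air_c"] = proj + (hourly_met["air_c"].to_numpy() - obs_daily.to_numpy())
    return out


@dataclass
class ScenarioBundle:
    """Model-ready inputs for one scenario, with transform provenance."""

    spec: ScenarioSpec
    landcover: pd.DataFrame
    met: pd.DataFrame
    boundary: pd.DataFrame  # passed through unmodified (constant lake boundary)
    provenance: dict = field(default_factory=dict)


def build_scenario(
    spec: ScenarioSpec,
    landcover: pd.DataFrame,
    met: pd.DataFrame,
    boundary: pd.DataFrame,
    delta: ClimateDelta = None,
    delta_seed: int = 0,
    buffer_width_m: float = DEFAULT_BUFFER_WIDTH_M,
    min_height_m: float = DEFAULT_MIN_HEIGHT_M,
) -> ScenarioBundle:
    """Vegetation treatment, then climate adjustment; boundary unchanged."""
    provenance = {"scenario": spec.name, "transforms": []}
    lc = modify_vegetation(landcover, spec.vegetation, buffer_width_m, min_height_m)
    provenance["transforms"].append(
        {"vegetation": spec.vegetation, "buffer_width_m": buffer_width_m,
         "min_height_m": min_height_m}
    )
    if spec.climate_period == "current":
        met_out = met.copy()
    else:
        if delta is None:
            delta = synthetic_delta(met, spec.climate_period, spec.rcp, seed=delta_seed)
        if not delta.covers(met.index.floor("D").unique()):
            raise ValueError("climate delta does not cover all simulation days")
        met_out = climate_adjust(met, delta)
        provenance["transforms"].append(
            {"climate_period": spec.climate_period, "rcp": spec.rcp,
             "delta_source": "synthetic" if delta.period else "external"}
        )
    provenance["transforms"].append({"boundary_water_temperature": "held constant"})
    return ScenarioBundle(
        spec=spec, landcover=lc, met=met_out, boundary=boundary.copy(), provenance=provenance
    )
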