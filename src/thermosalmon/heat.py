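"""1-D river temperature model: surface/bed flux assembly, explicit upwind
advection at a 2-minute step over 500 m nodes, and two-stage calibration.

Numerical scheme: explicit first-order upwind advection (no explicit
longitudinal dispersion; the upwind truncation term substitutes for it at
this grid scale), surface and bed fluxes applied as a per-depth source term,
and an analytic exponential update for the substrate-layer temperature.
Hourly output is the instantaneous value on the hour; an initial flush
period is discarded from output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import hydraulics
from .metrics import FitMetrics, fit_metrics

RHO_CP_WATER = 4.182e6  # J/m3/K
LATENT_HEAT_VAP = 2.45e6  # J/kg
RHO_WATER = 1000.0  # kg/m3
STEFAN = 5.670374419e-8  # W/m2/K4
WATER_EMISSIVITY = 0.96
ALBEDO = 0.05
BOWEN_COEFF = 0.61  # hPa/degC at sea-level pressure
SEA_LEVEL_PRESSURE = 1013.25  # hPa
PRESSURE_SCALE_HEIGHT = 8434.0  # m


@dataclass(frozen=True)
class SubstrateParams:
    """Streambed substrate/hyporheic parameterization.

    Defaults are the calibrated study values, taken verbatim including the
    printed sediment diffusivity/conductivity pair; ``physical_sediment()``
    returns the variant with those two values swapped (the printed pair is
    physically transposed: 1.54 W/m/degC and 0.0064 cm2/s are the plausible
    conductivity/diffusivity for alluvium).
    """

    layer_thickness: float = 0.12  # m
    hyporheic_pct: float = 0.0  # fraction of nodal streamflow exchanged
    porosity: float = 0.400
    thermal_diffusivity: float = 1.54  # cm2/s
    thermal_conductivity: float = 0.0064  # W/m/degC
    deep_alluvium_temp: float = 12.0  # degC
    label: str = "default"

    def __post_init__(self):
        if self.layer_thickness <= 0:
            raise ValueError("layer thickness must be > 0")
        if not 0.0 <= self.hyporheic_pct <= 1.0:
            raise ValueError("hyporheic_pct must lie in [0, 1]")
        if not 0.0 < self.porosity < 1.0:
            raise ValueError("porosity must lie in (0, 1)")

    @classmethod
    def physical_sediment(cls, **kw) -> "SubstrateParams":
        kw.setdefault("thermal_diffusivity", 0.0064)
        kw.setdefault("thermal_conductivity", 1.54)
        kw.setdefault("label", "physical")
        return cls(**kw)

    @property
    def sediment_heat_capacity(self) -> float:
        """Volumetric heat capacity of the sediment matrix, J/m3/K (k/alpha)."""
        return self.thermal_conductivity / (self.thermal_diffusivity * 1e-4)

    @property
    def layer_heat_capacity(self) -> float:
        """Areal heat capacity of the porosity-weighted substrate layer, J/m2/K."""
        vol = self.porosity * RHO_CP_WATER + (1.0 - self.porosity) * self.sediment_heat_capacity
        return self.layer_thickness * vol

    @property
    def conductance(self) -> float:
        """Conduction conductance over a half layer, W/m2/K."""
        return self.thermal_conductivity / (self.layer_thickness / 2.0)


@dataclass(frozen=True)
class EvaporationParams:
    wind_offset_coeff: float = 2.21e-9  # a, m/s per hPa of vapor deficit
    wind_slope_coeff: float = 0.0  # b, per (m/s wind)
    method: str = "mass transfer"

    def __post_init__(self):
        if self.wind_offset_coeff < 0 or self.wind_slope_coeff < 0:
            raise ValueError("evaporation coefficients must be >= 0")


@dataclass
class HeatFluxes:
    """Surface/bed energy fluxes, W/m2, positive into the water column."""

    shortwave: np.ndarray
    longwave_atm: np.ndarray
    back_radiation: np.ndarray
    latent: np.ndarray
    sensible: np.ndarray
    bed: np.ndarray

    def total(self):
        return (
            self.shortwave
            + self.longwave_atm
            + self.back_radiation
            + self.latent
            + self.sensible
            + self.bed
        )


@dataclass
class TemperatureField:
    """Hourly node x time water temperatures for the output window."""

    data: pd.DataFrame  # index: hourly timestamps, columns: node ids
    dx: float = 500.0
    dt: float = 120.0
    flush_days: int = 5

    def __post_init__(self):
        if not np.all(np.isfinite(self.data.to_numpy())):
            raise ValueError("temperature field contains non-finite values")

    def daily_mean(self) -> pd.DataFrame:
        return self.data.groupby(self.data.index.floor("D")).mean()

    def daily_max(self) -> pd.DataFrame:
        return self.data.groupby(self.data.index.floor("D")).max()


def saturation_vapor_pressure(t_c):
    """Magnus form, hPa."""
    t = np.asarray(t_c, dtype=float)
    return 6.1078 * 10.0 ** (7.5 * t / (237.3 + t))


def surface_fluxes(
    met_hour,
    water_t,
    shade_fraction,
    cloudiness,
    depth,
    evap: EvaporationParams = EvaporationParams(),
    view_to_sky=1.0,
    elevation_m: float = 50.0,
) -> HeatFluxes:
    """Assemble surface heat fluxes for one time slice (scalars or arrays).

    met_hour: mapping with air_c, rh_pct, wind_mps, solar_wm2.
    shortwave = (1 - albedo) * (direct*(1 - shade) + diffuse*view_to_sky),
    with diffuse fraction 0.3 + 0.7 C. Atmospheric longwave uses the
    Swinbank clear-sky emissivity with cloud enhancement (1 + 0.22 C^2);
    back radiation is -0.96 sigma (T_w + 273.15)^4. Latent heat follows the
    mass-transfer evaporation E = (a + b*wind) * (esat(T_w) - e_air) (hPa);
    sensible heat applies the Bowen ratio to the same wind function so both
    vanish together when the vapor and thermal gradients are zero.
    """
    ta = np.asarray(met_hour["air_c"], dtype=float)
    rh = np.asarray(met_hour["rh_pct"], dtype=float)
    wind = np.asarray(met_hour["wind_mps"], dtype=float)
    solar = np.asarray(met_hour["solar_wm2"], dtype=float)
    tw = np.asarray(water_t, dtype=float)
    c = np.clip(np.asarray(cloudiness, dtype=float), 0.0, 1.0)
    shade = np.asarray(shade_fraction, dtype=float)

    diffuse_frac = np.clip(0.3 + 0.7 * c, 0.0, 1.0)
    direct = solar * (1.0 - diffuse_frac)
    diffuse = solar * diffuse_frac
    shortwave = (1.0 - ALBEDO) * (direct * (1.0 - shade) + diffuse * np.asarray(view_to_sky, float))

    ta_k = ta + 273.15
    emiss_clear = 0.937e-5 * ta_k**2  # Swinbank (1963)
    emiss = np.minimum(emiss_clear * (1.0 + 0.22 * c**2), 1.0)
    longwave_atm = WATER_EMISSIVITY * emiss * STEFAN * ta_k**4

    back = -WATER_EMISSIVITY * STEFAN * (tw + 273.15) ** 4

    e_air = rh / 100.0 * saturation_vapor_pressure(ta)
    wind_fn = evap.wind_offset_coeff + evap.wind_slope_coeff * wind  # m/s per hPa
    evap_rate = wind_fn * (saturation_vapor_pressure(tw) - e_air)  # m/s
    latent = -RHO_WATER * LATENT_HEAT_VAP * evap_rate

    pressure = SEA_LEVEL_PRESSURE * math.exp(-max(elevation_m, 0.0) / PRESSURE_SCALE_HEIGHT)
    sensible = (
        -RHO_WATER
        * LATENT_HEAT_VAP
        * wind_fn
        * BOWEN_COEFF
        * (pressure / 1000.0)
        * (tw - ta)
    )

    zero = np.zeros_like(tw)
    return HeatFluxes(
        shortwave=shortwave,
        longwave_atm=np.broadcast_to(longwave_atm, tw.shape).copy() if tw.shape else longwave_atm,
        back_radiation=back,
        latent=latent,
        sensible=sensible,
        bed=zero,
    )


def bed_flux(
    substrate: SubstrateParams,
    water_t,
    substrate_t,
    dt: float = 120.0,
    discharge=None,
    width=None,
    dx: float = 500.0,
):
    """Bed conduction (+ optional hyporheic mixing) for one step.

    Conduction water<->substrate and substrate<->deep alluvium over half the
    layer thickness each; the substrate layer integrates forward with its
    porosity-weighted heat capacity via an exact exponential update. The
    hyporheic term routes ``hyporheic_pct`` of nodal streamflow through the
    substrate, exchanging heat at the substrate temperature.

    Returns (flux into water W/m2, next substrate temperature).
    """
    tw = np.asarray(water_t, dtype=float)
    ts = np.asarray(substrate_t, dtype=float)
    g = substrate.conductance
    g_hyp = 0.0
    if substrate.hyporheic_pct > 0 and discharge is not None and width is not None:
        g_hyp = (
            substrate.hyporheic_pct
            * np.asarray(discharge, dtype=float)
            * RHO_CP_WATER
            / (np.asarray(width, dtype=float) * dx)
        )
    g_w = g + g_hyp
    flux = g_w * (ts - tw)

    cap = substrate.layer_heat_capacity
    g_total = g_w + g
    t_eq = (g_w * tw + g * substrate.deep_alluvium_temp) / g_total
    decay = np.exp(-dt * g_total / cap)
    ts_next = t_eq + (ts - t_eq) * decay
    return flux, ts_next


def step_temperature(temps, total_flux, flow: hydraulics.FlowState, dt: float, dx: float,
                     inflow_temps=None):
    """One explicit step: upwind advection then flux heating.

    temps: per-node temperatures; total_flux: per-node W/m2 (positive into
    water). ``inflow_temps[j]``, when given, is the temperature of the water
    advected into node j (used for tributary junctions, where the upstream
    parcel is pre-mixed flow-weighted with the tributary inflow; element 0 is
    ignored). The upstream boundary node is advection-free here (the caller
    pins it to the boundary series). Raises on CFL violation.
    """
    t = np.asarray(temps, dtype=float)
    v = np.asarray(flow.velocity, dtype=float)
    courant = v * dt / dx
    if np.any(courant > 1.0):
        bad = int(np.argmax(courant))
        raise RuntimeError(
            f"CFL violation at node {bad}: velocity {v[bad]:.3f} m/s, "
            f"dt {dt} s, dx {dx} m (courant {courant[bad]:.3f})"
        )
    upstream = t[:-1] if inflow_temps is None else np.asarray(inflow_temps, float)[1:]
    out = t.copy()
    out[1:] = t[1:] - courant[1:] * (t[1:] - upstream)
    d = np.asarray(flow.depth, dtype=float)
    heat = np.where(d > 0, dt * np.asarray(total_flux, float) / (RHO_CP_WATER * np.maximum(d, 1e-9)), 0.0)
    return out + heat


@dataclass
class ModelConfig:
    """Site constants and numerical settings for run_model."""

    latitude: float = 47.4
    longitude: float = -124.0
    utc_offset: float = -8.0
    station_elevation_m: float = 50.0
    dt_seconds: float = 120.0
    flush_days: int = 5
    manning_n: float = hydraulics.DEFAULT_MANNING_N
    evaporation: EvaporationParams = field(default_factory=EvaporationParams)
    albedo: float = ALBEDO
    max_gap_hours: int = 3
    disable_surface_fluxes: bool = False  # testing hook: advection-only runs


def _check_hourly(name: str, idx: pd.DatetimeIndex, needed: pd.DatetimeIndex, max_gap: int):
    missing = needed.difference(idx)
    if len(missing) == 0:
        return
    # tolerate gaps of up to max_gap consecutive hours (callers interpolate)
    runs, run = [], 1
    for a, b in zip(missing[:-1], missing[1:]):
        if (b - a) == pd.Timedelta(hours=1):
            run += 1
        else:
            runs.append(run)
            run = 1
    runs.append(run)
    if max(runs) > max_gap:
        raise ValueError(
            f"{name}: missing forcing hours (longest gap {max(runs)} h > {max_gap} h), "
            f"first missing {missing[0]}"
        )


def _reindex_interp(df, needed, max_gap):
    out = df.reindex(needed.union(df.index)).interpolate(method="time", limit=max_gap)
    return out.loc[needed]


def run_model(
    reach: pd.DataFrame,
    met: pd.DataFrame,
    boundary: pd.DataFrame,
    tributaries,
    shade_series: pd.DataFrame,
    substrate: SubstrateParams,
    dates,
    config: ModelConfig = None,
    view_to_sky=None,
    cloudiness: pd.Series = None,
) -> TemperatureField:
    """Run the temperature model and return hourly output for the window.

    Parameters
    ----------
    reach : node table (node_id, rkm, elevation_m, gradient, width_m, ...).
    met : hourly air_c, rh_pct, wind_mps, solar_wm2 (+ optional cloudiness).
    boundary : hourly temp_c and q_cms at the upstream node.
    tributaries : iterable of hydraulics.TributarySpec.
    shade_series : hourly x node effective-shade fractions.
    dates : (start, end) of the output window; forcing must additionally
        cover the preceding flush period, which is excluded from output.
    """
    cfg = config or ModelConfig()
    start = pd.Timestamp(dates[0])
    end = pd.Timestamp(dates[1])
    comp_start = start - pd.Timedelta(days=cfg.flush_days)
    hours = pd.date_range(comp_start, end + pd.Timedelta(hours=23), freq="h")

    for name, df in (("met", met), ("boundary", boundary), ("shade", shade_series)):
        _check_hourly(name, df.index, hours, cfg.max_gap_hours)
    met = _reindex_interp(met, hours, cfg.max_gap_hours)
    boundary = _reindex_interp(boundary, hours, cfg.max_gap_hours)
    shade_series = _reindex_interp(shade_series, hours, cfg.max_gap_hours)

    n_nodes = len(reach)
    node_ids = reach["node_id"].to_numpy()
    widths = reach["width_m"].to_numpy(dtype=float)
    dx = float(np.median(np.abs(np.diff(reach["rkm"].to_numpy())) * 1000.0))

    # --- cloudiness -------------------------------------------------------
    if cloudiness is None:
        if "cloudiness" in met.columns:
            cloud = met["cloudiness"].to_numpy(dtype=float)
        else:
            from . import solar as _solar

            em = np.array(
                [
                    _solar.clear_sky_radiation(
                        _solar.solar_position(cfg.latitude, cfg.longitude, ts, cfg.utc_offset),
                        cfg.station_elevation_m,
                        ts.dayofyear,
                    )
                    for ts in hours
                ]
            )
            cloud = _solar.cloudiness_series(met["solar_wm2"].to_numpy(), np.where(em > 1.0, em, 0.0))
    else:
        cloud = cloudiness.reindex(hours).to_numpy(dtype=float)
    cloud = np.clip(np.nan_to_num(cloud), 0.0, 1.0)

    # --- hydraulics (hourly) ---------------------------------------------
    tribs = list(tributaries)
    q_boundary = boundary["q_cms"]
    discharge = hydraulics.route_flow(q_boundary, tribs, reach)
    depth_tbl, vel_tbl = hydraulics.manning_table(discharge, reach, cfg.manning_n)
    trib_nodes = hydraulics.assign_tributary_nodes(reach, tribs)
    trib_data = []
    for trib in tribs:
        t_series = trib.temperature
        if t_series is None:
            raise ValueError(f"tributary {trib.name} has no temperature series")
        _check_hourly(f"tributary {trib.name}", t_series.index, hours, cfg.max_gap_hours)
        t_arr = _reindex_interp(t_series.to_frame("t"), hours, cfg.max_gap_hours)["t"].to_numpy()
        trib_data.append((trib_nodes[trib.name], trib.fraction, t_arr))

    # --- per-hour forcing arrays -----------------------------------------
    met_air = met["air_c"].to_numpy(dtype=float)
    met_rh = met["rh_pct"].to_numpy(dtype=float)
    met_wind = met["wind_mps"].to_numpy(dtype=float)
    met_solar = met["solar_wm2"].to_numpy(dtype=float)
    bnd_t = boundary["temp_c"].to_numpy(dtype=float)
    bnd_q = q_boundary.reindex(hours).to_numpy(dtype=float)
    shade_arr = shade_series.to_numpy(dtype=float)
    if shade_arr.shape[1] != n_nodes:
        raise ValueError("shade series column count does not match reach nodes")
    vts = np.ones(n_nodes) if view_to_sky is None else np.asarray(view_to_sky, dtype=float)
    depth_arr = depth_tbl.to_numpy(dtype=float)
    vel_arr = vel_tbl.to_numpy(dtype=float)
    q_arr = discharge.to_numpy(dtype=float)

    dt = cfg.dt_seconds
    steps_per_hour = int(round(3600.0 / dt))
    if abs(steps_per_hour * dt - 3600.0) > 1e-9:
        raise ValueError("dt must divide one hour")
    n_hours = len(hours)
    n_steps = (n_hours - 1) * steps_per_hour + 1

    temps = np.full(n_nodes, bnd_t[0], dtype=float)
    t_sub = np.full(n_nodes, substrate.deep_alluvium_temp, dtype=float)
    out = np.empty((n_hours, n_nodes))
    out[0] = temps

    for k in range(1, n_steps):
        h = (k - 1) // steps_per_hour  # forcing slice held constant within hour
        frac = ((k - 1) % steps_per_hour + 1) / steps_per_hour
        flow = hydraulics.FlowState(
            discharge=q_arr[h], depth=depth_arr[h], velocity=vel_arr[h], width=widths,
            manning_n=cfg.manning_n,
        )

        if cfg.disable_surface_fluxes:
            total = np.zeros(n_nodes)
        else:
            met_hour = {
                "air_c": met_air[h], "rh_pct": met_rh[h],
                "wind_mps": met_wind[h], "solar_wm2": met_solar[h],
            }
            fluxes = surface_fluxes(
                met_hour, temps, shade_arr[h], cloud[h], depth_arr[h],
                evap=cfg.evaporation, view_to_sky=vts, elevation_m=cfg.station_elevation_m,
            )
            bed, t_sub = bed_flux(
                substrate, temps, t_sub, dt=dt,
                discharge=q_arr[h], width=widths, dx=dx,
            )
            fluxes.bed = bed
            total = fluxes.total()

        # junction mixing enters through the advected inflow: the parcel
        # arriving at a junction node is the flow-weighted mix of upstream
        # water and tributary inflow (scalar reference implementation:
        # hydraulics.mix_temperature)
        inflow = None
        if trib_data:
            inflow = np.empty_like(temps)
            inflow[1:] = temps[:-1]
            for node_idx, fraction, t_trib in trib_data:
                q_in = fraction * bnd_q[h]
                if q_in > 0 and node_idx > 0:
                    q_up = q_arr[h, node_idx] - q_in
                    inflow[node_idx] = (
                        q_up * temps[node_idx - 1] + q_in * t_trib[h]
                    ) / (q_up + q_in)

        temps = step_temperature(temps, total, flow, dt, dx, inflow_temps=inflow)

        # pin boundary node (linear interpolation between hourly values)
        t0 = bnd_t[h] * (1.0 - frac) + bnd_t[min(h + 1, n_hours - 1)] * frac
        temps[0] = t0

        if k % steps_per_hour == 0:
            out[k // steps_per_hour] = temps

    result = pd.DataFrame(out, index=hours, columns=node_ids)
    result = result.loc[(result.index >= start) & (result.index <= end + pd.Timedelta(hours=23))]
    return TemperatureField(data=result, dx=dx, dt=dt, flush_days=cfg.flush_days)


# ---------------------------------------------------------------------------
# calibration


def default_candidates(base: SubstrateParams = None) -> list:
    """The 8-candidate grid: substrate thickness x hyporheic exchange."""
    base = base or SubstrateParams()
    out = []
    for thickness in (0.12, 0.25, 0.5, 1.0):
        for hyp in (0.0, 0.02):
            out.append(
                replace(base, layer_thickness=thickness, hyporheic_pct=hyp,
                        label=f"t{thickness}_h{hyp}")
            )
    return out


@dataclass
class CalibrationResult:
    selected_index: int
    selected: SubstrateParams
    stage1: pd.DataFrame  # hourly metrics per candidate (averaged over stations)
    stage2: pd.DataFrame  # daily metrics for the two finalists
    fit_report: dict  # per-station hourly+daily metrics of the selection


def station_fit_report(field: TemperatureField, observations: pd.DataFrame) -> dict:
    """Per-station bias/RMSE/NSE at hourly and daily resolution."""
    report = {}
    pred = field.data
    if not observations.index.isin(pred.index).all():
        raise ValueError("observation timestamps are not aligned with model output hours")
    for station in observations.columns:
        if station not in pred.columns:
            raise ValueError(f"observation station {station!r} is not a model node")
        p = pred.loc[observations.index, station]
        o = observations[station]
        hourly = fit_metrics(p, o)
        pd_daily = p.groupby(p.index.floor("D")).mean()
        od_daily = o.groupby(o.index.floor("D")).mean()
        daily = fit_metrics(pd_daily, od_daily)
        report[str(station)] = {
            "hourly": {"bias_c": hourly.bias, "rmse_c": hourly.rmse, "nse": hourly.nse},
            "daily": {"bias_c": daily.bias, "rmse_c": daily.rmse, "nse": daily.nse},
        }
    return report


def _mean_metrics(field: TemperatureField, observations: pd.DataFrame, daily: bool):
    biases, rmses, nses = [], [], []
    pred = field.data
    for station in observations.columns:
        p = pred.loc[observations.index, station]
        o = observations[station]
        if daily:
            p = p.groupby(p.index.floor("D")).mean()
            o = o.groupby(o.index.floor("D")).mean()
        m = fit_metrics(p, o)
        biases.append(m.bias)
        rmses.append(m.rmse)
        nses.append(m.nse)
    return float(np.mean(biases)), float(np.mean(rmses)), float(np.mean(nses))


def calibrate(candidates, observations: pd.DataFrame, runner) -> CalibrationResult:
    """Two-stage candidate selection against station observations.

    Stage 1 runs every candidate through ``runner`` (callable
    SubstrateParams -> TemperatureField), scores hourly bias/RMSE/NSE
    averaged across stations and ranks by RMSE. Stage 2 rescores the two
    best on daily mean temperatures and selects the lower daily RMSE
    (ties: higher NSE, then lower |bias|, then first listed).
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates")
    fields = [runner(c) for c in candidates]
    if not observations.index.isin(fields[0].data.index).all():
        raise ValueError("observation timestamps are not aligned with model output hours")
    rows = []
    for i, (cand, fld) in enumerate(zip(candidates, fields)):
        bias, rmse, nse = _mean_metrics(fld, observations, daily=False)
        rows.append({"candidate": i, "label": cand.label, "bias_c": bias, "rmse_c": rmse, "nse": nse})
    stage1 = pd.DataFrame(rows).set_index("candidate")
    finalists = list(stage1.sort_values("rmse_c", kind="stable").index[:2])

    rows2 = []
    for i in finalists:
        bias, rmse, nse = _mean_metrics(fields[i], observations, daily=True)
        rows2.append({"candidate": i, "label": candidates[i].label, "bias_c": bias, "rmse_c": rmse, "nse": nse})
    stage2 = pd.DataFrame(rows2).set_index("candidate")
    ranked = sorted(
        stage2.itertuples(),
        key=lambda r: (round(r.rmse_c, 12), round(-r.nse, 12), round(abs(r.bias_c), 12), r.Index),
    )
    best = int(ranked[0].Index)
    return CalibrationResult(
        selected_index=best,
        selected=candidates[best],
        stage1=stage1,
        stage2=stage2,
        fit_report=station_fit_report(fields[best], observations),
    )
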