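"""Seeded synthetic rivers, meteorology, landcover and observation twins.

Generates inputs with the statistical structure of a warm, lake-fed coastal
river: an ~41 km reach at 500 m nodes, a warm boundary signal with a damped
diurnal cycle, six small tributaries (two above 2 % of main-stem flow), and
meteorology/vegetation fields inside the documented input ranges. All
randomness derives from one integer seed; every generator is independently
deterministic (component-keyed child generators, no global state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import heat, solar
from .hydraulics import TributarySpec

# component ids for child generators
_RNG_REACH, _RNG_MET, _RNG_BOUNDARY, _RNG_LANDCOVER, _RNG_GRIDS, _RNG_OBS = range(6)

RKM_UPSTREAM = 54.1
ELEV_RANGE = (8.5, 99.9)
WIDTH_RANGE = (22.7, 200.6)
TREE_HEIGHT_MAX = 82.3
TOPO_RANGE = (0.5, 52.5)
CANOPY_DENSITY_RANGE = (75.0, 90.0)
OVERHANG_RANGE = (0.0, 2.0)
DEFAULT_TRIB_FRACTIONS = (0.079, 0.024, 0.015, 0.012, 0.008, 0.005)


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_nodes: int = 82
    dx: float = 500.0  # m
    start_date: str = "2019-06-10"
    end_date: str = "2019-09-18"
    flush_days: int = 5
    met_ranges: dict = field(
        default_factory=lambda: {"air": (8.3, 31.9), "wind": (0.0, 12.1), "rh": (0.0, 100.0)}
    )
    boundary_mean: float = 20.4  # degC (warm lake-outlet summer mean)
    boundary_diurnal_amplitude: float = 0.4  # degC (damped, lake-outlet-like)
    boundary_seasonal_amplitude: float = 1.0  # degC over the season
    boundary_q_mean: float = 16.1  # m3/s
    tributary_fractions: tuple = DEFAULT_TRIB_FRACTIONS
    tributary_cooling: float = 3.0  # degC below boundary daily mean
    met_noise_sd: float = 0.3  # degC on hourly air temperature
    noise_sd: float = 0.1  # degC on twin observations
    latitude: float = 47.4
    longitude: float = -124.0
    utc_offset: float = -8.0
    station_elevation_m: float = 50.0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.dx <= 0:
            raise ValueError("dx must be > 0")
        if pd.Timestamp(self.end_date) < pd.Timestamp(self.start_date):
            raise ValueError("end_date must be >= start_date")
        if any(f < 0 for f in self.tributary_fractions):
            raise ValueError("tributary fractions must be >= 0")
        if not self.tributary_fractions:
            raise ValueError("tributary fractions must be non-empty")

    @property
    def dates(self) -> tuple:
        return (pd.Timestamp(self.start_date), pd.Timestamp(self.end_date))

    def hourly_index(self, include_flush: bool = True) -> pd.DatetimeIndex:
        start = self.dates[0]
        if include_flush:
            start = start - pd.Timedelta(days=self.flush_days)
        return pd.date_range(start, self.dates[1] + pd.Timedelta(hours=23), freq="h")

    def rng(self, component: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, component])


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.convolve(np.pad(x, window, mode="edge"), kernel, mode="same")[window:-window]


def make_reach(cfg: SyntheticConfig) -> pd.DataFrame:
    """Per-node channel/landcover table (rkm decreasing downstream)."""
    rng = cfg.rng(_RNG_REACH)
    n = cfg.n_nodes
    rkm = RKM_UPSTREAM - cfg.dx / 1000.0 * np.arange(n)

    # strictly decreasing elevation: positive random increments scaled to span
    drops = rng.uniform(0.2, 1.0, n - 1)
    drops *= (ELEV_RANGE[1] - ELEV_RANGE[0] - 1e-9) / drops.sum()  # keep min above bound
    elev = ELEV_RANGE[1] - np.concatenate([[0.0], np.cumsum(drops)])
    grad = np.empty(n)
    grad[1:] = drops / cfg.dx
    grad[0] = grad[1]

    width = np.clip(
        60.0 + 35.0 * _smooth(rng.standard_normal(n), 7) + 25.0 * np.sin(np.linspace(0, 3 * np.pi, n)),
        *WIDTH_RANGE,
    )
    aspect = (200.0 + 120.0 * np.sin(np.linspace(0, 2.5 * np.pi, n)) + rng.normal(0, 15, n)) % 360.0
    topo = {
        k: np.clip(base + rng.normal(0, 6.0, n), *TOPO_RANGE)
        for k, base in (("e", 18.0), ("s", 8.0), ("w", 20.0))
    }
    density = np.clip(rng.uniform(*CANOPY_DENSITY_RANGE, n), *CANOPY_DENSITY_RANGE)
    overhang = np.clip(rng.uniform(*OVERHANG_RANGE, n), *OVERHANG_RANGE)

    return pd.DataFrame(
        {
            "node_id": np.arange(n),
            "rkm": np.round(rkm, 4),
            "elevation_m": elev,
            "gradient": grad,
            "width_m": width,
            "aspect_deg": aspect,
            "topo_e_deg": topo["e"],
            "topo_s_deg": topo["s"],
            "topo_w_deg": topo["w"],
            "canopy_density_pct": density,
            "overhang_m": overhang,
        }
    )


def seasonal_air_trend(cfg: SyntheticConfig, index: pd.DatetimeIndex) -> np.ndarray:
    """Daily-mean air temperature trend (degC): warm mid-season hump."""
    t0 = (cfg.dates[0] - pd.Timedelta(days=cfg.flush_days)).dayofyear
    t1 = cfg.dates[1].dayofyear
    doy = index.dayofyear.to_numpy()
    frac = (doy - t0) / max(t1 - t0, 1)
    return 14.5 + 5.0 * np.sin(np.clip(frac, 0, 1) * math.pi) ** 2


def make_meteorology(cfg: SyntheticConfig) -> pd.DataFrame:
    """Hourly meteorology covering the flush + output window.

    Air temperature = seasonal trend + sinusoidal diurnal cycle peaking at
    15:00 + optional noise, clipped to the configured bounds; solar is a
    clear-sky curve times a stochastic cloud attenuation (1 - 0.65 C^2).
    """
    rng = cfg.rng(_RNG_MET)
    idx = cfg.hourly_index()
    hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    trend = seasonal_air_trend(cfg, idx)

    diurnal = 5.5 * np.sin(2 * math.pi * (hours - 9.0) / 24.0)  # peak 15:00
    noise = cfg.met_noise_sd * rng.standard_normal(len(idx)) if cfg.met_noise_sd > 0 else 0.0
    air = np.clip(trend + diurnal + noise, *cfg.met_ranges["air"])

    rh = np.clip(85.0 - 2.5 * diurnal + rng.normal(0, 4.0, len(idx)), *cfg.met_ranges["rh"])
    wind = np.clip(
        2.5 + 1.8 * np.sin(2 * math.pi * (hours - 10.0) / 24.0) + rng.gamma(2.0, 0.5, len(idx)) - 1.0,
        *cfg.met_ranges["wind"],
    )

    # stochastic cloudiness: clipped AR(1), range 0-0.87
    z = np.empty(len(idx))
    z[0] = rng.normal()
    eps = rng.standard_normal(len(idx))
    for i in range(1, len(idx)):
        z[i] = 0.97 * z[i - 1] + math.sqrt(1 - 0.97**2) * eps[i]
    cloud = np.clip(0.3 + 0.35 * z, 0.0, 0.87)

    clear = np.array(
        [
            solar.clear_sky_radiation(
                solar.solar_position(cfg.latitude, cfg.longitude, ts, cfg.utc_offset),
                cfg.station_elevation_m,
                ts.dayofyear,
            )
            for ts in idx
        ]
    )
    sw = clear * np.array([solar.cloud_attenuation(c) for c in cloud])

    return pd.DataFrame(
        {"air_c": air, "rh_pct": rh, "wind_mps": wind, "solar_wm2": sw}, index=idx
    )


def make_boundary_and_tributaries(cfg: SyntheticConfig):
    """Boundary temperature/discharge plus the six tributary specs.

    The boundary is a warm lake-outlet-like signal: configurable mean, small
    damped diurnal cycle peaking late afternoon, slow seasonal drift.
    Tributaries run cooler (boundary daily mean minus ``tributary_cooling``)
    with half the diurnal amplitude.
    """
    rng = cfg.rng(_RNG_BOUNDARY)
    idx = cfg.hourly_index()
    hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0
    n = len(idx)
    frac = np.arange(n) / max(n - 1, 1)

    seasonal = cfg.boundary_seasonal_amplitude * np.sin(math.pi * frac) ** 2
    diurnal = cfg.boundary_diurnal_amplitude * np.sin(2 * math.pi * (hours - 11.0) / 24.0)
    temp = cfg.boundary_mean + seasonal + diurnal

    q = np.maximum(
        cfg.boundary_q_mean * (1.0 + 0.25 * np.cos(math.pi * frac)) + _smooth(rng.normal(0, 0.4, n), 24),
        1.0,
    )
    boundary = pd.DataFrame({"temp_c": temp, "q_cms": q}, index=idx)

    daily_mean = pd.Series(temp, index=idx).groupby(idx.floor("D")).transform("mean").to_numpy()
    trib_temp_base = daily_mean - cfg.tributary_cooling + 0.5 * diurnal

    n_tribs = len(cfg.tributary_fractions)
    rkm_lo = RKM_UPSTREAM - (cfg.n_nodes - 1) * cfg.dx / 1000.0
    positions = np.linspace(RKM_UPSTREAM - 2.0, rkm_lo + 2.0, n_tribs) if n_tribs > 1 else [
        (RKM_UPSTREAM + rkm_lo) / 2.0
    ]
    tribs = []
    for i, fraction in enumerate(cfg.tributary_fractions):
        offset = rng.normal(0, 0.3)
        series = pd.Series(trib_temp_base + offset, index=idx, name=f"trib_{i+1}")
        tribs.append(
            TributarySpec(name=f"trib_{i+1}", rkm=float(round(positions[i], 3)),
                          fraction=float(fraction), temperature=series)
        )
    return boundary, tribs


def make_landcover(cfg: SyntheticConfig, reach: pd.DataFrame) -> pd.DataFrame:
    """Wide per-node vegetation transect table (7 directions x 10 samples)."""
    rng = cfg.rng(_RNG_LANDCOVER)
    n = len(reach)
    nt, ns = solar.N_TRANSECTS, solar.N_SAMPLES
    base = rng.uniform(8.0, 45.0, n)  # nodal canopy height
    heights = np.clip(
        base[:, None, None] * rng.uniform(0.4, 1.4, (n, nt, ns)), 0.0, TREE_HEIGHT_MAX
    )
    heights[rng.random((n, nt, ns)) < 0.15] = 0.0  # gaps
    dens = np.clip(
        reach["canopy_density_pct"].to_numpy()[:, None, None] / 100.0
        + rng.normal(0, 0.02, (n, nt, ns)),
        CANOPY_DENSITY_RANGE[0] / 100.0,
        CANOPY_DENSITY_RANGE[1] / 100.0,
    )
    dens[heights == 0.0] = 0.0
    out = {"node_id": reach["node_id"].to_numpy()}
    for i in range(nt):
        for j in range(ns):
            out[f"veg_d{i+1}_s{j+1}_height_m"] = heights[:, i, j]
    for i in range(nt):
        for j in range(ns):
            out[f"veg_d{i+1}_s{j+1}_density"] = dens[:, i, j]
    return pd.DataFrame(out)


def make_height_grids(
    cfg: SyntheticConfig,
    shape=(200, 200),
    cell_size: float = 3.0,
    canopy_height: float = 0.0,
    channel_halfwidth: float = 30.0,
    walls=(),
    ridges=(),
):
    """Vegetation-height and ground-elevation grids around a straight channel.

    The channel runs along the y axis, centered at x = 0. ``walls`` is an
    iterable of (x_offset_m, height_m) vegetation features occupying one
    cell-wide north-south strips; ``ridges`` the same for ground elevation.
    Returns (height_grid, elevation_grid) as solar.Grid objects (default
    3 m cells, 9.0 m2 cell area).
    """
    if cell_size <= 0:
        raise ValueError("grid cell size must be > 0")
    ny, nx = shape
    origin = (-(nx // 2) * cell_size, -(ny // 2) * cell_size)
    xs = origin[0] + cell_size * np.arange(nx)

    veg = np.full((ny, nx), float(canopy_height))
    veg[:, np.abs(xs) <= channel_halfwidth] = 0.0  # riverbank mask
    for x_off, h in walls:
        col = int(round((x_off - origin[0]) / cell_size))
        if 0 <= col < nx:
            veg[:, col] = h

    elev = np.zeros((ny, nx))
    for x_off, h in ridges:
        col = int(round((x_off - origin[0]) / cell_size))
        if 0 <= col < nx:
            elev[:, col] = h
    return solar.Grid(veg, cell_size, origin), solar.Grid(elev, cell_size, origin)


def station_nodes(cfg: SyntheticConfig, n_stations: int = 6) -> np.ndarray:
    """Evenly spaced monitoring nodes (boundary node excluded)."""
    return np.unique(np.linspace(1, cfg.n_nodes - 1, n_stations).round().astype(int))


@dataclass
class SyntheticDataset:
    """Everything needed to run the temperature model, from one seed."""

    cfg: SyntheticConfig
    reach: pd.DataFrame
    landcover: pd.DataFrame
    met: pd.DataFrame
    boundary: pd.DataFrame
    tributaries: list
    shade: pd.DataFrame
    view_to_sky: np.ndarray


def make_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    reach = make_reach(cfg)
    landcover = make_landcover(cfg, reach)
    met = make_meteorology(cfg)
    boundary, tribs = make_boundary_and_tributaries(cfg)
    shade, vts = solar.build_shade_series(
        reach, landcover, cfg.hourly_index(), cfg.latitude, cfg.longitude, cfg.utc_offset
    )
    return SyntheticDataset(cfg, reach, landcover, met, boundary, tribs, shade, vts)


def run_truth(dataset: SyntheticDataset, truth_params: heat.SubstrateParams) -> heat.TemperatureField:
    cfg = dataset.cfg
    model_cfg = heat.ModelConfig(
        latitude=cfg.latitude,
        longitude=cfg.longitude,
        utc_offset=cfg.utc_offset,
        station_elevation_m=cfg.station_elevation_m,
        flush_days=cfg.flush_days,
    )
    return heat.run_model(
        dataset.reach,
        dataset.met,
        dataset.boundary,
        dataset.tributaries,
        dataset.shade,
        truth_params,
        cfg.dates,
        config=model_cfg,
        view_to_sky=dataset.view_to_sky,
    )


def make_observation_twin(
    truth_params: heat.SubstrateParams,
    cfg: SyntheticConfig,
    n_stations: int = 6,
    noise_seed: int = None,
    dataset: SyntheticDataset = None,
):
    """Noisy virtual-station observations from a known-truth model run.

    Runs the heat-budget model with ``truth_params`` on the seeded synthetic
    inputs, samples ``n_stations`` node locations and adds i.i.d. Gaussian
    noise of sd ``cfg.noise_sd``. Returns (observations, truth) where truth
    carries the parameterization, the full field and the dataset, for
    parameter-recovery tests. ``noise_seed`` decouples the noise draw from
    the input seed (default: derived from cfg.seed).
    """
    dataset = dataset or make_dataset(cfg)
    field = run_truth(dataset, truth_params)
    nodes = station_nodes(cfg, n_stations)
    clean = field.data[nodes]
    rng = np.random.default_rng(
        [cfg.seed, _RNG_OBS] if noise_seed is None else [noise_seed, _RNG_OBS]
    )
    noise = rng.normal(0.0, cfg.noise_sd, clean.shape) if cfg.noise_sd > 0 else 0.0
    obs = clean + noise
    truth = {"params": truth_params, "field": field, "dataset": dataset, "stations": nodes}
    return obs, truth
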