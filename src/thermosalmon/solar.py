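"""Solar geometry, clear-sky radiation, cloudiness inversion, and riparian shading.

The shading model follows the transect-sampling convention used by 1-D stream
temperature models: per node, topographic shade angles in the east, south and
west directions, and seven radial vegetation transects (bearings 45..315
degrees in 45-degree steps) with ten samples spaced ten meters apart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

SOLAR_CONSTANT = 1367.0  # W/m2
#: Broadband clear-sky atmospheric transmissivity (zenith path, sea level).
DEFAULT_TRANSMISSIVITY = 0.75
#: Scale height used for the pressure correction of optical air mass (m).
PRESSURE_SCALE_HEIGHT = 8434.0

#: Bearings (degrees clockwise from north) of the 7 vegetation transects.
TRANSECT_BEARINGS = (45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
N_TRANSECTS = 7
N_SAMPLES = 10
SAMPLE_SPACING_M = 10.0

#: Bearings of the three topographic shade directions (east, south, west).
TOPO_BEARINGS = {"e": 90.0, "s": 180.0, "w": 270.0}

#: Default attenuation polynomial: E_o/E_m = 1 - 0.65 C^2.
DEFAULT_CLOUD_COEFFS = (1.0, 0.0, -0.65)


@dataclass(frozen=True)
class SolarPosition:
    """Sun position for one instant.

    altitude/azimuth in degrees; azimuth clockwise from north.
    """

    altitude: float
    azimuth: float
    declination: float
    hour_angle: float

    def __post_init__(self):
        if not -90.0 <= self.altitude <= 90.0:
            raise ValueError(f"altitude out of range: {self.altitude}")
        if not 0.0 <= self.azimuth < 360.0:
            raise ValueError(f"azimuth out of range: {self.azimuth}")


@dataclass
class ShadeGeometry:
    """Per-node shading description.

    topo_angles: mapping {'e','s','w'} -> degrees.
    veg_heights / veg_densities: (7, 10) arrays; sample j of transect i lies
    at distance 10*(j+1) m from the bank along bearing TRANSECT_BEARINGS[i].
    """

    topo_angles: dict = field(default_factory=lambda: {"e": 0.0, "s": 0.0, "w": 0.0})
    veg_heights: np.ndarray = field(default_factory=lambda: np.zeros((N_TRANSECTS, N_SAMPLES)))
    veg_densities: np.ndarray = field(default_factory=lambda: np.zeros((N_TRANSECTS, N_SAMPLES)))
    overhang: float = 0.0

    def __post_init__(self):
        self.veg_heights = np.asarray(self.veg_heights, dtype=float)
        self.veg_densities = np.asarray(self.veg_densities, dtype=float)
        if self.veg_heights.shape != (N_TRANSECTS, N_SAMPLES):
            raise ValueError(f"veg_heights must be {(N_TRANSECTS, N_SAMPLES)}")
        if self.veg_densities.shape != (N_TRANSECTS, N_SAMPLES):
            raise ValueError(f"veg_densities must be {(N_TRANSECTS, N_SAMPLES)}")
        for k, v in self.topo_angles.items():
            if not 0.0 <= v < 90.0:
                raise ValueError(f"topo angle {k}={v} outside [0, 90)")
        if np.any(self.veg_densities < 0) or np.any(self.veg_densities > 1):
            raise ValueError("canopy densities must lie in [0, 1]")

    @property
    def sample_distances(self) -> np.ndarray:
        return SAMPLE_SPACING_M * np.arange(1, N_SAMPLES + 1, dtype=float)

    def view_to_sky(self) -> float:
        """Fraction of sky hemisphere open above the channel (0..1).

        One minus the mean blocked fraction over the seven transects, where
        each transect blocks max(sample angular height)/90 of its sector.
        Used to attenuate diffuse shortwave.
        """
        dist = self.sample_distances
        angles = np.degrees(np.arctan2(self.veg_heights, dist))
        blocked = angles.max(axis=1) / 90.0
        return float(1.0 - blocked.mean())


@dataclass(frozen=True)
class CloudEstimate:
    cloudiness: float
    eo: float
    em: float

    def __post_init__(self):
        if not 0.0 <= self.cloudiness <= 1.0:
            raise ValueError("cloudiness must lie in [0, 1]")
        if self.em < 0:
            raise ValueError("modeled maximum radiation must be >= 0")


def solar_position(latitude: float, longitude: float, timestamp, utc_offset: float) -> SolarPosition:
    """Sun altitude/azimuth from the NOAA general solar position equations.

    Parameters
    ----------
    latitude, longitude : degrees (longitude positive east).
    timestamp : datetime-like (naive, local clock time).
    utc_offset : hours ahead of UTC (negative west). Fixed offset, no DST.

    Documented accuracy is better than 0.5 degrees for years 1950-2050.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"invalid latitude {latitude}")
    import pandas as pd

    ts = pd.Timestamp(timestamp)
    doy = ts.dayofyear
    hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    n_days = 366 if ts.is_leap_year else 365

    # Fractional year (radians), centered mid-hour per NOAA convention.
    gamma = 2.0 * math.pi / n_days * (doy - 1 + (hours - 12.0) / 24.0)

    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )  # minutes
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )  # radians

    time_offset = eqtime + 4.0 * longitude - 60.0 * utc_offset  # minutes
    tst = hours * 60.0 + time_offset  # true solar time, minutes
    ha = tst / 4.0 - 180.0  # degrees

    lat_r = math.radians(latitude)
    ha_r = math.radians(ha)
    cos_zen = math.sin(lat_r) * math.sin(decl) + math.cos(lat_r) * math.cos(decl) * math.cos(ha_r)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zen = math.acos(cos_zen)
    altitude = 90.0 - math.degrees(zen)

    sin_zen = math.sin(zen)
    if sin_zen < 1e-9:
        azimuth = 180.0
    else:
        cos_t = (math.sin(lat_r) * cos_zen - math.sin(decl)) / (math.cos(lat_r) * sin_zen)
        cos_t = min(1.0, max(-1.0, cos_t))
        theta = math.degrees(math.acos(cos_t))  # angle from due south
        # Morning (hour angle <= 0): sun east of south; afternoon: west.
        azimuth = 180.0 - theta if ha <= 0 else 180.0 + theta
    return SolarPosition(
        altitude=altitude,
        azimuth=azimuth % 360.0,
        declination=math.degrees(decl),
        hour_angle=ha,
    )


def eccentricity_factor(day_of_year: int) -> float:
    """Earth-sun distance correction to the solar constant."""
    return 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)


def clear_sky_radiation(
    pos: SolarPosition,
    elevation_m: float = 0.0,
    day_of_year: int = 172,
    transmissivity: float = DEFAULT_TRANSMISSIVITY,
) -> float:
    """Clear-sky global shortwave at the surface, W/m2.

    E = S0 * ecc(doy) * tau^m * sin(alt), with optical air mass
    m = (P/P0) / sin(alt) and P/P0 = exp(-z / 8434 m). Returns 0 for the sun
    at or below the horizon.
    """
    if pos.altitude <= 0.0:
        return 0.0
    sin_alt = math.sin(math.radians(pos.altitude))
    pressure_ratio = math.exp(-max(elevation_m, 0.0) / PRESSURE_SCALE_HEIGHT)
    air_mass = pressure_ratio / sin_alt
    return SOLAR_CONSTANT * eccentricity_factor(day_of_year) * transmissivity**air_mass * sin_alt


def cloud_attenuation(cloudiness: float, coefficients=DEFAULT_CLOUD_COEFFS) -> float:
    """Forward attenuation model: E_o/E_m as a polynomial in cloudiness C.

    coefficients are (c0, c1, c2, ...) for c0 + c1*C + c2*C^2 + ...; the
    default is 1 - 0.65 C^2. Cubic coefficients may be supplied via config.
    """
    return float(sum(c * cloudiness**i for i, c in enumerate(coefficients)))


def cloudiness_from_radiation(eo: float, em: float, coefficients=DEFAULT_CLOUD_COEFFS) -> CloudEstimate:
    """Invert the attenuation relation E_o/E_m = f(C) for cloudiness C.

    Root is bracketed on [0, 1]; ratios outside the attainable range clamp to
    the nearer endpoint. Requires em > 0 (daylight).
    """
    if eo < 0:
        raise ValueError("observed radiation must be >= 0")
    if em <= 0:
        raise ValueError("modeled maximum radiation must be > 0 during daylight")
    ratio = eo / em
    f0, f1 = cloud_attenuation(0.0, coefficients), cloud_attenuation(1.0, coefficients)
    lo, hi = (f1, f0) if f1 < f0 else (f0, f1)
    if ratio >= hi:
        c = 0.0 if f0 >= f1 else 1.0
    elif ratio <= lo:
        c = 1.0 if f0 >= f1 else 0.0
    else:
        c = brentq(lambda x: cloud_attenuation(x, coefficients) - ratio, 0.0, 1.0, xtol=1e-8)
    return CloudEstimate(cloudiness=min(1.0, max(0.0, c)), eo=eo, em=em)


def cloudiness_series(eo: np.ndarray, em: np.ndarray, coefficients=DEFAULT_CLOUD_COEFFS) -> np.ndarray:
    """Vectorized cloudiness with night carry-forward.

    Hours with em <= 0 (night) carry the last daylight estimate forward;
    leading night hours before any daylight default to 0.
    """
    eo = np.asarray(eo, dtype=float)
    em = np.asarray(em, dtype=float)
    out = np.empty_like(eo)
    last = 0.0
    for i in range(eo.size):
        if em[i] > 0:
            last = cloudiness_from_radiation(eo[i], em[i], coefficients).cloudiness
        out[i] = last
    return out


@dataclass
class Grid:
    """Axis-aligned raster: values[row, col], row -> +y, col -> +x (meters).

    origin is the (x, y) of the center of cell [0, 0]. Queries outside the
    grid return 0 (treated as flat/bare beyond coverage).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def sample(self, x: float, y: float) -> float:
        col = int(round((x - self.origin[0]) / self.cell_size))
        row = int(round((y - self.origin[1]) / self.cell_size))
        if 0 <= row < self.values.shape[0] and 0 <= col < self.values.shape[1]:
            return float(self.values[row, col])
        return 0.0

    def contains(self, x: float, y: float) -> bool:
        col = int(round((x - self.origin[0]) / self.cell_size))
        row = int(round((y - self.origin[1]) / self.cell_size))
        return 0 <= row < self.values.shape[0] and 0 <= col < self.values.shape[1]


def _bearing_to_dxdy(bearing_deg: float) -> tuple:
    b = math.radians(bearing_deg)
    return math.sin(b), math.cos(b)  # x east, y north


def _topo_angle_along(elev_grid: Grid, x0, y0, z0, bearing, near_cells=25, far_m=20000.0):
    """Topographic shade angle: max(near-field over first `near_cells` cells,
    far-field out to `far_m`)."""
    dx, dy = _bearing_to_dxdy(bearing)
    step = elev_grid.cell_size
    near_limit = near_cells * step

    def best_angle(d_from, d_to):
        best = 0.0
        d = max(d_from, step)
        while d <= d_to:
            z = elev_grid.sample(x0 + dx * d, y0 + dy * d)
            if z > z0:
                best = max(best, math.degrees(math.atan2(z - z0, d)))
            d += step
        return best

    near = best_angle(step, near_limit)
    far = best_angle(step, far_m)  # far-field maxima include the near cells
    return max(near, far)


def sample_landcover(
    height_grid: Grid,
    elevation_grid: Grid,
    node_xy: tuple,
    channel_aspect: float = 0.0,
    near_cells: int = 25,
    far_distance_m: float = 20000.0,
) -> ShadeGeometry:
    """Sample topographic shade angles and vegetation transects at a node.

    Topographic angle per direction (east/south/west) is the larger of the
    near-field angle over the first `near_cells` cells and the far-field
    angle out to `far_distance_m`. Vegetation is sampled on 7 radial
    transects x 10 samples at 10 m spacing. `channel_aspect` rotates transect
    bearings with the channel (0 = channel flowing north-south).
    """
    x0, y0 = node_xy
    if not elevation_grid.contains(x0, y0):
        raise ValueError(f"node {node_xy} outside elevation grid")
    z0 = elevation_grid.sample(x0, y0)

    topo = {
        k: min(_topo_angle_along(elevation_grid, x0, y0, z0, (b + channel_aspect) % 360.0,
                                 near_cells, far_distance_m), 89.999)
        for k, b in TOPO_BEARINGS.items()
    }

    heights = np.zeros((N_TRANSECTS, N_SAMPLES))
    for i, bearing in enumerate(TRANSECT_BEARINGS):
        dx, dy = _bearing_to_dxdy((bearing + channel_aspect) % 360.0)
        for j in range(N_SAMPLES):
            d = SAMPLE_SPACING_M * (j + 1)
            heights[i, j] = height_grid.sample(x0 + dx * d, y0 + dy * d)
    densities = np.where(heights > 0, 1.0, 0.0)
    return ShadeGeometry(topo_angles=topo, veg_heights=heights, veg_densities=densities)


def _nearest_direction(bearings, azimuth: float) -> int:
    """Index of the bearing angularly closest to azimuth; ties toward south."""
    diffs = [abs((b - azimuth + 180.0) % 360.0 - 180.0) for b in bearings]
    best = min(diffs)
    tied = [i for i, d in enumerate(diffs) if abs(d - best) < 1e-9]
    if len(tied) == 1:
        return tied[0]
    return min(tied, key=lambda i: abs(bearings[i] - 180.0))


def effective_shade(geom: ShadeGeometry, pos: SolarPosition, width_m: float) -> float:
    """Fraction of the direct solar beam blocked at the channel center (0-1).

    Returns 0 with the sun below the horizon (no direct beam exists), 1 when
    the topographic angle in the direction nearest the solar azimuth is at or
    above the solar altitude, and otherwise the combined vegetation
    attenuation 1 - prod(1 - density_i) over transect samples (in the
    transect nearest the solar azimuth) whose angular height from the channel
    center exceeds the solar altitude.
    """
    if pos.altitude <= 0.0:
        return 0.0
    topo_keys = list(TOPO_BEARINGS.keys())
    tdir = _nearest_direction([TOPO_BEARINGS[k] for k in topo_keys], pos.azimuth)
    if geom.topo_angles[topo_keys[tdir]] >= pos.altitude:
        return 1.0
    vdir = _nearest_direction(TRANSECT_BEARINGS, pos.azimuth)
    dist = geom.sample_distances + max(width_m, 0.0) / 2.0 - geom.overhang
    dist = np.maximum(dist, 0.5)
    angles = np.degrees(np.arctan2(geom.veg_heights[vdir], dist))
    blocking = angles > pos.altitude
    if not blocking.any():
        return 0.0
    transmitted = np.prod(1.0 - geom.veg_densities[vdir][blocking])
    return float(1.0 - transmitted)


# ---------------------------------------------------------------------------
# landcover-table bridge


def landcover_columns() -> list:
    """Column names of the wide per-node landcover table (70 + 70)."""
    cols = []
    for i in range(1, N_TRANSECTS + 1):
        for j in range(1, N_SAMPLES + 1):
            cols.append(f"veg_d{i}_s{j}_height_m")
    for i in range(1, N_TRANSECTS + 1):
        for j in range(1, N_SAMPLES + 1):
            cols.append(f"veg_d{i}_s{j}_density")
    return cols


def geometry_from_tables(reach_row, landcover_row) -> ShadeGeometry:
    """Build a ShadeGeometry from one reach row + one landcover row."""
    heights = np.empty((N_TRANSECTS, N_SAMPLES))
    dens = np.empty((N_TRANSECTS, N_SAMPLES))
    for i in range(N_TRANSECTS):
        for j in range(N_SAMPLES):
            heights[i, j] = landcover_row[f"veg_d{i+1}_s{j+1}_height_m"]
            dens[i, j] = landcover_row[f"veg_d{i+1}_s{j+1}_density"]
    return ShadeGeometry(
        topo_angles={
            "e": float(reach_row["topo_e_deg"]),
            "s": float(reach_row["topo_s_deg"]),
            "w": float(reach_row["topo_w_deg"]),
        },
        veg_heights=heights,
        veg_densities=dens,
        overhang=float(reach_row.get("overhang_m", 0.0)),
    )


def build_shade_series(
    reach, landcover, hours, latitude: float, longitude: float, utc_offset: float
):
    """Hourly x node effective-shade table plus per-node view-to-sky.

    Returns (shade DataFrame indexed by `hours`, view_to_sky ndarray).
    """
    import pandas as pd

    geoms = [
        geometry_from_tables(reach.iloc[i], landcover.iloc[i]) for i in range(len(reach))
    ]
    widths = reach["width_m"].to_numpy(dtype=float)
    vts = np.array([g.view_to_sky() for g in geoms])
    shade = np.zeros((len(hours), len(geoms)))
    for h, ts in enumerate(hours):
        pos = solar_position(latitude, longitude, ts, utc_offset)
        if pos.altitude <= 0:
            continue
        for i, g in enumerate(geoms):
            shade[h, i] = effective_shade(g, pos, widths[i])
    return pd.DataFrame(shade, index=hours, columns=reach["node_id"].to_numpy()), vts
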