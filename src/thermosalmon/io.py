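"""CSV/YAML/JSON dialects for all pipeline artifacts.

Timestamps are written ISO-8601 with an explicit UTC offset and parsed back
to naive local wall time (the model runs on fixed-offset local standard
time). Reads validate schemas and report the offending row/column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import solar
from .hydraulics import TributarySpec

REACH_COLUMNS = [
    "node_id", "rkm", "elevation_m", "gradient", "width_m", "aspect_deg",
    "topo_e_deg", "topo_s_deg", "topo_w_deg", "canopy_density_pct", "overhang_m",
]
MET_COLUMNS = ["air_c", "rh_pct", "wind_mps", "solar_wm2"]
BOUNDARY_COLUMNS = ["temp_c", "q_cms"]


def _offset_str(utc_offset: float) -> str:
    sign = "-" if utc_offset < 0 else "+"
    h = int(abs(utc_offset))
    m = int(round((abs(utc_offset) - h) * 60))
    return f"{sign}{h:02d}:{m:02d}"


def format_timestamps(index: pd.DatetimeIndex, utc_offset: float) -> list:
    off = _offset_str(utc_offset)
    return [ts.strftime("%Y-%m-%dT%H:%M:%S") + off for ts in index]


def parse_timestamps(values, source: str) -> pd.DatetimeIndex:
    out = []
    for i, v in enumerate(values):
        try:
            ts = pd.Timestamp(v)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{source}: malformed timestamp at row {i + 2}: {v!r}") from exc
        if ts.tz is not None:
            ts = ts.tz_localize(None)
        out.append(ts)
    return pd.DatetimeIndex(out)


def _require_columns(df: pd.DataFrame, cols, source: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}")


def write_timeseries(df: pd.DataFrame, path, utc_offset: float = -8.0):
    out = df.copy()
    out.insert(0, "timestamp", format_timestamps(df.index, utc_offset))
    out.to_csv(path, index=False)


def read_timeseries(path, columns=None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["timestamp"], path.name)
    idx = parse_timestamps(df["timestamp"].tolist(), path.name)
    df = df.drop(columns=["timestamp"])
    if columns is not None:
        _require_columns(df, columns, path.name)
    df.index = idx
    return df


def write_reach(reach: pd.DataFrame, path):
    reach[REACH_COLUMNS].to_csv(path, index=False)


def read_reach(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, REACH_COLUMNS, Path(path).name)
    return df


def write_landcover(landcover: pd.DataFrame, path):
    landcover.to_csv(path, index=False)


def read_landcover(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["node_id"] + solar.landcover_columns(), Path(path).name)
    return df


def write_met(met: pd.DataFrame, path, utc_offset: float = -8.0):
    write_timeseries(met[MET_COLUMNS], path, utc_offset)


def read_met(path) -> pd.DataFrame:
    return read_timeseries(path, MET_COLUMNS)


def write_boundary(boundary: pd.DataFrame, path, utc_offset: float = -8.0):
    write_timeseries(boundary[BOUNDARY_COLUMNS], path, utc_offset)


def read_boundary(path) -> pd.DataFrame:
    return read_timeseries(path, BOUNDARY_COLUMNS)


def write_tributaries(tributaries, directory, utc_offset: float = -8.0):
    """tributaries.csv plus one temperature CSV per tributary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for trib in tributaries:
        temp_path = directory / f"trib_{trib.name}.csv"
        write_timeseries(trib.temperature.to_frame("temp_c"), temp_path, utc_offset)
        rows.append(
            {"name": trib.name, "rkm": trib.rkm, "fraction": trib.fraction,
             "temperature_csv": temp_path.name}
        )
    pd.DataFrame(rows).to_csv(directory / "tributaries.csv", index=False)


def read_tributaries(directory) -> list:
    directory = Path(directory)
    table = pd.read_csv(directory / "tributaries.csv")
    _require_columns(table, ["name", "rkm", "fraction", "temperature_csv"], "tributaries.csv")
    out = []
    for _, row in table.iterrows():
        temps = read_timeseries(directory / row["temperature_csv"], ["temp_c"])["temp_c"]
        out.append(
            TributarySpec(name=row["name"], rkm=float(row["rkm"]),
                          fraction=float(row["fraction"]), temperature=temps)
        )
    return out


def write_temps(field, path, utc_offset: float = -8.0):
    """Wide temperature matrix: timestamp column then one column per node."""
    data = getattr(field, "data", field)
    write_timeseries(data, path, utc_offset)


def read_temps(path) -> pd.DataFrame:
    df = read_timeseries(path)
    df.columns = [int(c) if str(c).isdigit() else c for c in df.columns]
    return df


def write_growth(trajectories, path):
    rows = []
    for traj in trajectories:
        prev = None
        for date, mass in traj.mass.items():
            delta = mass - prev if prev is not None else mass - traj.mass.iloc[0]
            rows.append(
                {"node_id": traj.node_id, "date": pd.Timestamp(date).date().isoformat(),
                 "mass_g": mass, "delta_g": delta}
            )
            prev = mass
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_yaml(obj, path):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
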