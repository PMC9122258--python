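"""Steady low-flow routing and rectangular-channel hydraulics.

Summer baseflow is treated as steady within each hour: tributaries accrue as
fixed fractions of the gaged boundary flow, discharge is piecewise-constant
between junctions, and depth/velocity come from Manning's equation for a
rectangular channel (side slope z = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

DEFAULT_MANNING_N = 0.035


@dataclass
class FlowState:
    """Per-node hydraulic state for one time slice."""

    discharge: np.ndarray  # m3/s
    depth: np.ndarray  # m
    velocity: np.ndarray  # m/s
    width: np.ndarray  # m
    manning_n: float = DEFAULT_MANNING_N
    side_slope_z: float = 0.0


@dataclass(frozen=True)
class TributarySpec:
    name: str
    rkm: float
    fraction: float
    temperature: pd.Series | None = None  # hourly degC

    def __post_init__(self):
        if self.fraction < 0:
            raise ValueError(f"tributary {self.name}: negative flow fraction")
        if self.fraction >= 1:
            raise ValueError(f"tributary {self.name}: fraction must be < 1")


def tributary_inflow(boundary_q: pd.Series, fraction: float) -> pd.Series:
    """Hourly inflow as a constant fraction of the gaged boundary flow."""
    if fraction < 0:
        raise ValueError("flow fraction must be >= 0")
    if fraction >= 1:
        raise ValueError("flow fraction must be < 1")
    return boundary_q * fraction


def assign_tributary_nodes(reach: pd.DataFrame, tributaries) -> dict:
    """Map each tributary to the index of the nearest node at/below its rkm.

    Node rkm decreases downstream; a tributary joins at the first node whose
    rkm is <= the tributary rkm.
    """
    rkm = reach["rkm"].to_numpy()
    out = {}
    for trib in tributaries:
        if not (rkm.min() <= trib.rkm <= rkm.max()):
            raise ValueError(
                f"tributary {trib.name} at rkm {trib.rkm} outside reach "
                f"[{rkm.min()}, {rkm.max()}]"
            )
        idx = int(np.argmax(rkm <= trib.rkm))
        out[trib.name] = idx
    return out


def route_flow(boundary_q: pd.Series, tributaries, reach: pd.DataFrame) -> pd.DataFrame:
    """Node x hour discharge: boundary plus all inflows at/above each node."""
    node_of = assign_tributary_nodes(reach, tributaries)
    n_nodes = len(reach)
    add = np.zeros(n_nodes)
    for trib in tributaries:
        frac_add = np.zeros(n_nodes)
        frac_add[node_of[trib.name]:] = trib.fraction
        add += frac_add
    q = np.outer(boundary_q.to_numpy(), 1.0 + add)
    return pd.DataFrame(q, index=boundary_q.index, columns=reach["node_id"].to_numpy())


def manning_depth_velocity(q: float, width: float, slope: float, n: float = DEFAULT_MANNING_N):
    """Solve Manning's equation for a rectangular channel.

    q = (1/n) * (w*d) * R^(2/3) * S^(1/2) with R = w*d / (w + 2d); returns
    (depth, velocity). q = 0 gives (0, 0).
    """
    if q < 0:
        raise ValueError("discharge must be >= 0")
    if width <= 0 or slope <= 0:
        raise ValueError("width and slope must be > 0")
    if q == 0:
        return 0.0, 0.0

    sqrt_s = np.sqrt(slope)

    def resid(d):
        area = width * d
        r = area / (width + 2.0 * d)
        return area * r ** (2.0 / 3.0) * sqrt_s / n - q

    hi = 1.0
    while resid(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError(
                f"Manning solve failed to bracket: q={q}, width={width}, slope={slope}, n={n}"
            )
    depth = brentq(resid, 0.0, hi, xtol=1e-12, rtol=1e-12)
    velocity = q / (width * depth)
    return depth, velocity


def manning_table(discharge: pd.DataFrame, reach: pd.DataFrame, n: float = DEFAULT_MANNING_N):
    """Depth and velocity for every node/hour of a routed discharge table.

    Vectorized Newton iteration on the Manning residual (same equation as
    :func:`manning_depth_velocity`, which remains the scalar reference
    implementation).
    """
    q = discharge.to_numpy(dtype=float)
    w = np.broadcast_to(reach["width_m"].to_numpy(dtype=float), q.shape)
    s = np.broadcast_to(reach["gradient"].to_numpy(dtype=float), q.shape)
    if np.any(s <= 0) or np.any(w <= 0):
        raise ValueError("width and slope must be > 0 at every node")
    k = np.sqrt(s) / n
    # wide-channel starting guess: q ~ k * w * d^(5/3)
    d = np.maximum((np.maximum(q, 1e-12) / (k * w)) ** 0.6, 1e-6)
    for _ in range(60):
        area = w * d
        per = w + 2.0 * d
        r = area / per
        f = k * area * r ** (2.0 / 3.0) - q
        df = k * (w * r ** (2.0 / 3.0) + area * (2.0 / 3.0) * r ** (-1.0 / 3.0) * (w / per) ** 2)
        step = f / df
        d = np.maximum(d - step, 1e-9)
        if np.max(np.abs(step)) < 1e-12:
            break
    else:
        raise RuntimeError("Manning iteration did not converge")
    d = np.where(q <= 0, 0.0, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(d > 0, q / (w * d), 0.0)
    idx, cols = discharge.index, discharge.columns
    return (
        pd.DataFrame(d, index=idx, columns=cols),
        pd.DataFrame(v, index=idx, columns=cols),
    )


def mix_temperature(main_q, main_t, trib_q, trib_t):
    """Flow-weighted junction temperature (degC)."""
    main_q = np.asarray(main_q, dtype=float)
    trib_q = np.asarray(trib_q, dtype=float)
    if np.any(main_q < 0) or np.any(trib_q < 0):
        raise ValueError("flows must be >= 0")
    total = main_q + trib_q
    if np.any(total <= 0):
        raise ValueError("zero total flow at junction")
    return (main_q * np.asarray(main_t, float) + trib_q * np.asarray(trib_t, float)) / total
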