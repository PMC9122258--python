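"""Wisconsin bioenergetics energy balance for juvenile salmonids.

Daily growth is the energy mass balance Growth = Consumption - Metabolism -
Waste, evaluated on daily mean water temperature with species parameter sets
loaded from YAML data files (see ``thermosalmon/species/``). Rates are
specific (per gram of fish per day); energy bookkeeping is in J/g/d and
respiration is converted from g O2 with an oxycalorific coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

#: Joules per gram of oxygen respired (Wisconsin-model convention).
DEFAULT_OXYCAL = 13560.0

#: Mass floor (g); trajectories are clipped here and flagged.
MASS_FLOOR_G = 0.1

REGISTRY_SPECIES = ("chinook", "coho", "sockeye", "steelhead", "cutthroat")


@dataclass
class SpeciesParams:
    """Parameter set for one species (transcribed from published sources)."""

    name: str
    consumption: dict
    respiration: dict
    waste: dict
    sda_coeff: float
    oxycal: float = DEFAULT_OXYCAL
    common_name: str = ""

    def __post_init__(self):
        if self.consumption["CA"] <= 0:
            raise ValueError("CA must be > 0")
        if self.respiration["RA"] <= 0:
            raise ValueError("RA must be > 0")


@dataclass
class BioeInputs:
    """Run-level inputs (defaults follow the juvenile-Chinook growth setup)."""

    start_mass: float = 5.0  # g
    p_cmax: float = 0.5  # proportion of maximum consumption
    ed_pred: float = 4.7  # predator energy density, kJ/g
    ed_prey: float = 3.0  # prey energy density, kJ/g

    def __post_init__(self):
        if not 0.0 <= self.p_cmax <= 1.0:
            raise ValueError("p_cmax must lie in [0, 1]")
        if self.ed_pred <= 0 or self.ed_prey <= 0:
            raise ValueError("energy densities must be > 0")
        if self.start_mass <= 0:
            raise ValueError("start mass must be > 0")


@dataclass
class GrowthTrajectory:
    node_id: object
    mass: pd.Series  # daily mass, g
    specific_growth: pd.Series  # g/g/d
    final_change: float  # g
    hit_floor: bool = False


def load_species(name: str) -> SpeciesParams:
    """Load a registry species parameter file by name (e.g. 'chinook')."""
    key = name.lower()
    ref = resources.files("thermosalmon").joinpath(f"species/{key}.yaml")
    if not ref.is_file():
        raise KeyError(f"unknown species {name!r}; registry: {REGISTRY_SPECIES}")
    raw = yaml.safe_load(ref.read_text())
    return SpeciesParams(
        name=raw["species"],
        common_name=raw.get("common_name", ""),
        consumption=raw["consumption"],
        respiration=raw["respiration"],
        waste=raw["waste"],
        sda_coeff=raw["sda_coeff"],
        oxycal=raw.get("oxycal", DEFAULT_OXYCAL),
    )


def registry() -> dict:
    return {name: load_species(name) for name in REGISTRY_SPECIES}


def cmax(mass: float, params: SpeciesParams) -> float:
    """Maximum specific consumption CA * mass^CB (g prey / g fish / d).

    The temperature dependence is applied separately via
    :func:`f_temp_consumption`.
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    c = params.consumption
    return c["CA"] * mass ** c["CB"]


def _thornton_lessem(t, CQ, CTO, CTM, CTL, CK1, CK4):
    # Double-sigmoid: rising logistic anchored at (CQ, CK1) saturating by CTO,
    # falling logistic anchored at (CTL, CK4) from CTM.
    g1 = (1.0 / (CTO - CQ)) * math.log((0.98 * (1.0 - CK1)) / (CK1 * 0.02))
    g2 = (1.0 / (CTL - CTM)) * math.log((0.98 * (1.0 - CK4)) / (CK4 * 0.02))
    l1 = np.exp(np.clip(g1 * (np.asarray(t, float) - CQ), -700, 700))
    l2 = np.exp(np.clip(g2 * (CTL - np.asarray(t, float)), -700, 700))
    ka = CK1 * l1 / (1.0 + CK1 * (l1 - 1.0))
    kb = CK4 * l2 / (1.0 + CK4 * (l2 - 1.0))
    return ka * kb


def _kitchell_dome(t, CQ, CTO, CTM):
    t = np.asarray(t, float)
    v = (CTM - t) / (CTM - CTO)
    z = math.log(CQ) * (CTM - CTO)
    y = math.log(CQ) * (CTM - CTO + 2.0)
    x = (z**2 * (1.0 + math.sqrt(1.0 + 40.0 / y)) ** 2) / 400.0
    with np.errstate(invalid="ignore"):
        out = np.where(v > 0, v**x * np.exp(x * (1.0 - v)), 0.0)
    return out


def f_temp_consumption(t_c, params: SpeciesParams):
    """Temperature dependence of consumption, clamped to [0, 1].

    Supported forms: 'exponential', 'dome' (Kitchell), 'thornton_lessem'.
    """
    c = params.consumption
    form = c.get("form", "thornton_lessem")
    if form == "thornton_lessem":
        f = _thornton_lessem(t_c, c["CQ"], c["CTO"], c["CTM"], c["CTL"], c["CK1"], c["CK4"])
    elif form == "dome":
        f = _kitchell_dome(t_c, c["CQ"], c["CTO"], c["CTM"])
    elif form == "exponential":
        f = np.exp(c["CQ"] * np.asarray(t_c, float))
    else:
        raise ValueError(f"unknown consumption form {form!r}")
    out = np.clip(f, 0.0, 1.0)
    return float(out) if np.isscalar(t_c) else out


def _f_respiration(t_c, mass, params: SpeciesParams):
    """Specific respiration, g O2 / g fish / d."""
    r = params.respiration
    form = r.get("form", "exponential")
    base = r["RA"] * mass ** r["RB"] * np.exp(r["RQ"] * np.asarray(t_c, float))
    if form == "swim_speed":
        # Stewart et al. activity multiplier via swimming speed (cm/s).
        t = np.asarray(t_c, float)
        vel = np.where(
            t > r["RTL"],
            r["RK1"] * mass ** r["RK4"],
            r["ACT"] * mass ** r["RK4"] * np.exp(r["BACT"] * t),
        )
        act = np.exp(r["RTO"] * vel)
    elif form == "exponential":
        act = r.get("ACT", 1.0)
    else:
        raise ValueError(f"unknown respiration form {form!r}")
    return base * act


def daily_energy_ledger(mass, t_c, inputs: BioeInputs, params: SpeciesParams) -> dict:
    """All terms of the daily energy balance, J per g fish per day.

    Specific rates (g prey/g/d): consumption C = Cmax * p * f(T); egestion F
    per the configured egestion form; excretion U = UA * T^UB * e^(UG p) *
    (C - F); SDA = sda_coeff * (C - F). Respiration is converted to energy
    with the oxycalorific coefficient.
    """
    p = inputs.p_cmax
    ed_prey = inputs.ed_prey * 1000.0  # J/g
    c_spec = cmax(mass, params) * p * f_temp_consumption(t_c, params)

    w = params.waste
    eg_form = w.get("egestion_form", "elliott")
    if eg_form == "constant":
        pf = w["FA"]
    elif eg_form in ("elliott", "indigestible"):
        pe = w["FA"] * t_c ** w["FB"] * math.exp(w["FG"] * p)
        if eg_form == "indigestible":
            pff = w.get("indigestible_fraction", 0.0)
            pf = ((pe - 0.1) / 0.9) * (1.0 - pff) + pff
        else:
            pf = pe
    else:
        raise ValueError(f"unknown egestion form {eg_form!r}")
    f_spec = pf * c_spec

    ex_form = w.get("excretion_form", "elliott")
    if ex_form == "constant":
        u_spec = w["UA"] * (c_spec - f_spec)
    elif ex_form == "elliott":
        u_spec = w["UA"] * t_c ** w["UB"] * math.exp(w["UG"] * p) * (c_spec - f_spec)
    else:
        raise ValueError(f"unknown excretion form {ex_form!r}")

    sda_spec = params.sda_coeff * (c_spec - f_spec)
    r_spec = float(_f_respiration(t_c, mass, params))

    consumption_e = c_spec * ed_prey
    egestion_e = f_spec * ed_prey
    excretion_e = u_spec * ed_prey
    sda_e = sda_spec * ed_prey
    respiration_e = r_spec * params.oxycal
    growth_e = consumption_e - egestion_e - excretion_e - sda_e - respiration_e
    return {
        "consumption": consumption_e,
        "egestion": egestion_e,
        "excretion": excretion_e,
        "sda": sda_e,
        "respiration": respiration_e,
        "growth": growth_e,
    }


def daily_growth(mass, t_c, inputs: BioeInputs, params: SpeciesParams) -> float:
    """Daily change in mass (g/day) for a fish of the given mass at t_c."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    ledger = daily_energy_ledger(mass, t_c, inputs, params)
    ed_pred = inputs.ed_pred * 1000.0  # J/g
    return ledger["growth"] * mass / ed_pred


def simulate_growth(
    daily_temps: pd.Series, inputs: BioeInputs, params: SpeciesParams, node_id=None
) -> GrowthTrajectory:
    """Forward daily integration of the energy balance over a temperature series."""
    temps = daily_temps.to_numpy(dtype=float)
    if not np.all(np.isfinite(temps)):
        raise ValueError("non-finite temperature in growth input")
    mass = np.empty(temps.size)
    spec = np.empty(temps.size)
    m = inputs.start_mass
    hit_floor = False
    for i, t in enumerate(temps):
        dm = daily_growth(m, t, inputs, params)
        spec[i] = dm / m
        m = m + dm
        if m < MASS_FLOOR_G:
            m = MASS_FLOOR_G
            hit_floor = True
        mass[i] = m
    return GrowthTrajectory(
        node_id=node_id,
        mass=pd.Series(mass, index=daily_temps.index, name="mass_g"),
        specific_growth=pd.Series(spec, index=daily_temps.index, name="g_per_g_day"),
        final_change=float(mass[-1] - inputs.start_mass),
        hit_floor=hit_floor,
    )


def batch_growth(field, inputs: BioeInputs, params: SpeciesParams):
    """One growth trajectory per node of an hourly temperature field.

    ``field`` is a TemperatureField or a wide hourly DataFrame (columns =
    node ids). The daily driver is the daily mean of hourly temperatures.
    Returns (trajectories, summary) with summary = mean/sd of final mass
    change across nodes.
    """
    data = getattr(field, "data", field)
    if data.shape[1] == 0:
        raise ValueError("temperature field has no nodes")
    daily = data.groupby(data.index.floor("D") if hasattr(data.index, "floor") else data.index).mean()
    trajectories = [
        simulate_growth(daily[col], inputs, params, node_id=col) for col in daily.columns
    ]
    changes = np.array([t.final_change for t in trajectories])
    summary = {
        "n_nodes": int(len(trajectories)),
        "mean_change_g": float(changes.mean()),
        "sd_change_g": float(changes.std(ddof=1)) if len(changes) > 1 else 0.0,
    }
    return trajectories, summary


def zero_growth_temperature(
    p_cmax: float, inputs: BioeInputs, params: SpeciesParams, t_max: float = 35.0
) -> float:
    """Largest temperature with zero daily growth, above the growth optimum.

    Scans downward from t_max for the warmest sign change of daily growth at
    the starting mass and bisects it to 0.01 degC.
    """
    if not 0.0 < p_cmax <= 1.0:
        raise ValueError("p_cmax must lie in (0, 1]")
    run = BioeInputs(
        start_mass=inputs.start_mass, p_cmax=p_cmax, ed_pred=inputs.ed_pred, ed_prey=inputs.ed_prey
    )

    def g(t):
        return daily_growth(run.start_mass, t, run, params)

    ts = np.linspace(t_max, 1.0, 800)
    for i in range(ts.size - 1):
        if g(ts[i]) <= 0.0 < g(ts[i + 1]):
            return float(brentq(g, ts[i + 1], ts[i], xtol=0.001))
    raise ValueError(
        f"no zero-growth crossing found below {t_max} degC for p={p_cmax} ({params.name})"
    )


def growth_curve(
    params: SpeciesParams,
    inputs: BioeInputs,
    t_range,
    p_levels=(0.5,),
) -> pd.DataFrame:
    """Daily growth (g/d at the starting mass) across a temperature grid.

    Returns a tidy table with columns species, p_cmax, temp_c, growth_g_d.
    """
    t_range = np.asarray(t_range, dtype=float)
    if not np.all(np.isfinite(t_range)):
        raise ValueError("temperature grid must be finite")
    rows = []
    for p in p_levels:
        run = BioeInputs(
            start_mass=inputs.start_mass, p_cmax=p, ed_pred=inputs.ed_pred, ed_prey=inputs.ed_prey
        )
        for t in t_range:
            rows.append(
                {
                    "species": params.name,
                    "p_cmax": p,
                    "temp_c": float(t),
                    "growth_g_d": daily_growth(run.start_mass, float(t), run, params),
                }
            )
    return pd.DataFrame(rows)
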