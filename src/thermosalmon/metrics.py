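"""Summary statistics: model fit, 7DADM, threshold exceedance, scenario ANOVA.

7DADM uses local calendar days (midnight day boundary) and a trailing
right-labeled 7-day window; both conventions are fixed here and configurable
where they appear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FitMetrics:
    bias: float  # mean(pred - obs), degC
    rmse: float  # degC
    nse: float  # dimensionless, (-inf, 1]; nan when obs variance is zero


@dataclass(frozen=True)
class ThresholdSpec:
    label: str
    lower_c: float
    upper_c: float
    statistic: str = "daily_max"  # or "daily_mean"


#: Life-stage temperature thresholds for Pacific salmon and trout.
THRESHOLDS = (
    ThresholdSpec("smoltification", 12.0, 15.0),
    ThresholdSpec("embryo_development", 12.0, 15.0),
    ThresholdSpec("spawning_migration", 19.0, 23.0),
    ThresholdSpec("mortality", 24.0, 26.0),
)


def fit_metrics(pred: pd.Series, obs: pd.Series) -> FitMetrics:
    """Bias, RMSE and Nash-Sutcliffe efficiency of predictions vs observations."""
    if len(pred) != len(obs):
        raise ValueError("prediction and observation series differ in length")
    if len(pred) < 2:
        raise ValueError("need at least 2 points")
    if isinstance(pred, pd.Series) and isinstance(obs, pd.Series):
        if not pred.index.equals(obs.index):
            raise ValueError("prediction and observation timestamps are not aligned")
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    err = p - o
    bias = float(err.mean())
    rmse = float(np.sqrt((err**2).mean()))
    denom = float(((o - o.mean()) ** 2).sum())
    if denom == 0.0:
        nse = float("nan")  # undefined: zero observed variance
    else:
        nse = 1.0 - float((err**2).sum()) / denom
    return FitMetrics(bias=bias, rmse=rmse, nse=nse)


def daily_statistic(hourly: pd.Series, stat: str = "max", min_hours: int = 24) -> pd.Series:
    """Per-local-calendar-day statistic of an hourly series.

    Days with fewer than ``min_hours`` samples are dropped with a warning.
    """
    days = hourly.index.floor("D")
    grouped = hourly.groupby(days)
    counts = grouped.count()
    agg = grouped.max() if stat == "max" else grouped.mean()
    complete = counts >= min_hours
    if not complete.all():
        warnings.warn(
            f"excluding {int((~complete).sum())} incomplete day(s) from daily {stat}",
            stacklevel=2,
        )
    return agg[complete]


def sevendadm(hourly: pd.Series, window: int = 7):
    """Seven-day average daily maximum series and its period maximum.

    Daily maxima over local calendar days, then a trailing right-labeled
    mean over ``window`` days; the first value falls on day ``window``.
    Returns (series, period_max).
    """
    dmax = daily_statistic(hourly, "max")
    if len(dmax) < window:
        raise ValueError(f"need at least {window} complete days, have {len(dmax)}")
    series = dmax.rolling(window).mean().dropna()
    return series, float(series.max())


def sevendadm_table(field) -> pd.DataFrame:
    """7DADM per node for an hourly temperature field (wide DataFrame)."""
    data = getattr(field, "data", field)
    return pd.DataFrame({col: sevendadm(data[col])[0] for col in data.columns})


def exceedance_frequency(hourly: pd.Series, threshold_c: float, statistic: str = "daily_max") -> float:
    """Percent of complete days whose daily max (or mean) exceeds threshold."""
    stat = "max" if statistic == "daily_max" else "mean"
    daily = daily_statistic(hourly, stat)
    if len(daily) == 0:
        raise ValueError("no complete days in series")
    return 100.0 * float((daily > threshold_c).sum()) / float(len(daily))


def exceedance_table(field, thresholds=THRESHOLDS) -> pd.DataFrame:
    """Exceedance percentages per node against each registered threshold's
    lower bound."""
    data = getattr(field, "data", field)
    rows = []
    for spec in thresholds:
        for col in data.columns:
            rows.append(
                {
                    "node_id": col,
                    "threshold_label": spec.label,
                    "threshold_c": spec.lower_c,
                    "pct_days": exceedance_frequency(data[col], spec.lower_c, spec.statistic),
                }
            )
    return pd.DataFrame(rows)


def scenario_growth_anova(growth: pd.DataFrame) -> dict:
    """Two-way fixed-effects ANOVA of growth on climate x vegetation.

    ``growth`` needs columns climate, vegetation, change_g, with >= 2
    replicates (nodes) per cell. Returns per-term sums of squares, df, F and
    p-values.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("climate", "vegetation", "change_g"):
        if col not in growth.columns:
            raise ValueError(f"growth table missing column {col!r}")
    cells = growth.groupby(["climate", "vegetation"]).size()
    full = len(growth["climate"].unique()) * len(growth["vegetation"].unique())
    if len(cells) < full or (cells < 2).any():
        raise ValueError("every climate x vegetation cell needs >= 2 replicates")
    model = smf.ols("change_g ~ C(climate) * C(vegetation)", data=growth).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    key_map = {
        "C(climate)": "climate",
        "C(vegetation)": "vegetation",
        "C(climate):C(vegetation)": "interaction",
        "Residual": "residual",
    }
    for raw, name in key_map.items():
        row = table.loc[raw]
        out[name] = {
            "sum_sq": float(row["sum_sq"]),
            "df": float(row["df"]),
            "F": None if np.isnan(row["F"]) else float(row["F"]),
            "p": None if np.isnan(row["PR(>F)"]) else float(row["PR(>F)"]),
        }
    return out


def scenario_report(outputs: dict, current_key: str = "current") -> dict:
    """Comparison tables across scenario outputs.

    ``outputs`` maps scenario name -> {"field": hourly wide DataFrame,
    "growth_summary": {...}}. Returns per-node max-7DADM deltas vs the
    current scenario, reach-average deltas, growth summaries, and exceedance
    tables, all JSON/CSV-serializable.
    """
    if current_key not in outputs:
        raise ValueError(f"current scenario {current_key!r} missing from outputs")

    def max7(field):
        table = sevendadm_table(field)
        return table.max(axis=0)

    base = max7(outputs[current_key]["field"])
    report = {"scenarios": {}, "current": current_key}
    for name, out in outputs.items():
        m7 = max7(out["field"])
        delta = m7 - base
        report["scenarios"][name] = {
            "max_sevendadm_c": {str(k): float(v) for k, v in m7.items()},
            "delta_max_sevendadm_c": {str(k): float(v) for k, v in delta.items()},
            "reach_mean_delta_c": float(delta.mean()),
            "growth_summary": out.get("growth_summary"),
            "exceedance": exceedance_table(out["field"]).to_dict(orient="records"),
        }
    return report
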