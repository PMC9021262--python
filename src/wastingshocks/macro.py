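"""Income levels -> lagged growth shocks -> the shock x prevalence regressor.

Growth is simple percent change of per-capita levels. The interaction
regressor multiplies a country's long-run mean prevalence (as a proportion)
by growth in units of a 10% change, so the fitted coefficient reads directly
as a percent change in prevalence per 10% change in income.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "annual_growth",
    "long_run_mean_prevalence",
    "shock_regressor",
]

logger = logging.getLogger(__name__)

MEASURES = ("gni", "gdp")


def _level_column(measure: str) -> str:
    if measure not in MEASURES:
        raise ValidationError(f"measure must be one of {MEASURES}, got {measure!r}")
    return f"{measure}_pc"


def annual_growth(macro: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Percent annual growth per country-year: 100 * (Y_t - Y_{t-1}) / Y_{t-1}.

    Accepts either level columns (``gni_pc`` / ``gdp_pc``, preferred) or
    pre-computed growth columns (``gni_growth`` / ``gdp_growth``). Growth is
    missing (NaN), never zero, for years without a prior-year level.
    """
    level_col = _level_column(measure)
    growth_col = f"{measure}_growth"
    out = macro.loc[:, ["country", "year"]].copy()
    if level_col in macro.columns:
        levels = macro[level_col].to_numpy(dtype=float)
        if np.any(levels[np.isfinite(levels)] <= 0):
            raise ValidationError(f"{level_col} contains non-positive levels")
        df = macro.sort_values(["country", "year"]).reset_index()
        prev = df.groupby("country", sort=False)[level_col].shift(1)
        prev_year = df.groupby("country", sort=False)["year"].shift(1)
        consecutive = df["year"] - prev_year == 1
        growth = 100.0 * (df[level_col] - prev) / prev
        growth[~consecutive.fillna(False)] = np.nan
        out = df.loc[:, ["country", "year"]].copy()
        out["growth"] = growth.to_numpy()
        return out.reset_index(drop=True)
    if growth_col in macro.columns:
        out["growth"] = macro[growth_col].to_numpy(dtype=float)
        return out
    raise ValidationError(
        f"macro table has neither {level_col!r} nor {growth_col!r} columns"
    )


def long_run_mean_prevalence(
    children: pd.DataFrame,
    indicator: str,
    weight_col: str = "design_weight",
) -> pd.Series:
    """Per-country long-run prevalence in percent.

    Survey-weighted prevalence is computed within each round, then averaged
    across a country's rounds with equal round weight.
    """
    if children.empty:
        raise ValidationError("children table is empty")
    if indicator not in children.columns:
        raise ValidationError(f"indicator column {indicator!r} not found")
    df = children.loc[:, ["country", "round_id", indicator, weight_col]].dropna(
        subset=[indicator]
    )
    w = df[weight_col]
    wy = df[indicator] * w
    per_round = (
        pd.DataFrame({"country": df["country"], "round_id": df["round_id"], "wy": wy, "w": w})
        .groupby(["country", "round_id"], sort=True)
        .sum(numeric_only=True)
    )
    round_prev = 100.0 * per_round["wy"] / per_round["w"]
    return round_prev.groupby("country").mean().rename(f"mean_prev_{indicator}")


def shock_regressor(
    children: pd.DataFrame,
    macro: pd.DataFrame,
    mean_prev: pd.Series,
    measure: str,
    lag: int = 1,
) -> pd.Series:
    """Per-child interaction value: mean_prev_c (proportion) * g_{c, t-lag} / 10.

    ``mean_prev`` is percent-scale per country (as produced by
    :func:`long_run_mean_prevalence` or stored in country metadata) and is
    converted to a proportion here. Children whose country lacks growth for
    ``interview_year - lag`` get NaN; callers drop and count them.
    """
    growth = annual_growth(macro, measure).set_index(["country", "year"])["growth"]
    g = (
        pd.MultiIndex.from_arrays(
            [children["country"], children["interview_year"] - lag]
        )
        .map(growth)
        .to_numpy(dtype=float)
    )
    prev = children["country"].map(mean_prev).to_numpy(dtype=float)
    if np.isnan(prev).any():
        missing = sorted(set(children.loc[np.isnan(prev), "country"]))
        raise ValidationError(f"mean prevalence missing for countries: {missing[:5]}")
    value = (prev / 100.0) * g / 10.0
    n_missing = int(np.isnan(g).sum())
    if n_missing:
        logger.warning(
            "shock_regressor: %d children lack growth for interview_year - %d",
            n_missing,
            lag,
        )
    return pd.Series(value, index=children.index, name="shock")
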