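"""Burden projection: growth shocks x elasticity -> prevalence and counts.

Applies an estimated elasticity to country-level growth shocks (2020 growth
minus the 2010-2019 mean) to project next-year wasting prevalence and the
change in the number of wasted children, with regional and total
aggregation. Counts are carried at full float precision; rounding is a
display concern only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "DEFAULT_ELASTICITY",
    "compute_shock",
    "project_prevalence",
    "project_counts",
    "aggregate_counts",
]

logger = logging.getLogger(__name__)

#: Moderate/severe wasting elasticity of GDP shocks (main projection run);
#: the GNI companion value is -0.144.
DEFAULT_ELASTICITY = -0.178
GNI_ELASTICITY = -0.144


def compute_shock(g2020: float, g_decade_mean: float) -> float:
    """Growth shock in percent: crisis-year growth minus the decade mean."""
    g2020 = float(g2020)
    g_decade_mean = float(g_decade_mean)
    if not (np.isfinite(g2020) and np.isfinite(g_decade_mean)):
        raise ValidationError("shock inputs must be finite")
    return g2020 - g_decade_mean


def project_prevalence(prev2019, shock, elasticity: float = DEFAULT_ELASTICITY):
    """Projected prevalence in percent: prev * (1 + elasticity * shock / 10).

    Clamped to [0, 100]; clamping is logged when it bites. Accepts scalars
    or arrays.
    """
    prev = np.asarray(prev2019, dtype=float)
    shock = np.asarray(shock, dtype=float)
    raw = prev * (1.0 + elasticity * shock / 10.0)
    clipped = np.clip(raw, 0.0, 100.0)
    n_clamped = int(np.sum(raw != clipped))
    if n_clamped:
        logger.warning("project_prevalence: clamped %d projections to [0, 100]", n_clamped)
    return float(clipped) if clipped.ndim == 0 else clipped


def project_counts(
    rows: pd.DataFrame,
    elasticity: float = DEFAULT_ELASTICITY,
    elasticity_ci: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-country projections plus regional/total aggregates.

    ``rows`` needs columns country, g2020, g_decade_mean, prev2019, pop_u5
    and optionally grouping (empty/missing values collapse to "all").
    Returns ``(countries, aggregates)``; aggregate prevalences are
    population-weighted and counts are exact sums of the country rows.
    """
    if rows.empty:
        raise ValidationError("projection input is empty")
    required = {"country", "g2020", "g_decade_mean", "prev2019", "pop_u5"}
    missing = required - set(rows.columns)
    if missing:
        raise ValidationError(f"projection input missing columns: {sorted(missing)}")
    if rows["country"].duplicated().any():
        dupes = sorted(rows.loc[rows["country"].duplicated(), "country"].unique())
        raise ValidationError(f"duplicate countries in projection input: {dupes}")
    if (rows["pop_u5"] <= 0).any():
        raise ValidationError("pop_u5 must be positive")
    bad_prev = ~rows["prev2019"].between(0.0, 100.0)
    if bad_prev.any():
        raise ValidationError("prev2019 must lie in [0, 100]")

    out = rows.copy()
    if "grouping" not in out.columns:
        out["grouping"] = "all"
    out["grouping"] = out["grouping"].replace("", np.nan).fillna("all")

    out["shock"] = out["g2020"].astype(float) - out["g_decade_mean"].astype(float)
    out["prev2021"] = project_prevalence(
        out["prev2019"].to_numpy(), out["shock"].to_numpy(), elasticity
    )
    out["wasted2019"] = out["prev2019"] / 100.0 * out["pop_u5"]
    out["wasted2021"] = out["prev2021"] / 100.0 * out["pop_u5"]
    out["change"] = out["wasted2021"] - out["wasted2019"]
    if elasticity_ci is not None:
        lo_e, hi_e = sorted(elasticity_ci)
        for tag, e in (("lo", lo_e), ("hi", hi_e)):
            prev = project_prevalence(
                out["prev2019"].to_numpy(), out["shock"].to_numpy(), e
            )
            out[f"prev2021_{tag}"] = prev
            out[f"change_{tag}"] = prev / 100.0 * out["pop_u5"] - out["wasted2019"]

    aggregates = aggregate_counts(out)
    return out, aggregates


def aggregate_counts(rows: pd.DataFrame) -> pd.DataFrame:
    """Sum wasted-child counts by grouping plus a total row.

    Count columns are exact sums of the input rows; shock and prevalence
    columns, where present, are population-weighted means. This is the same
    aggregation used for the per-country projection output, so printed
    per-region count rows can be re-aggregated directly.
    """
    if rows.empty:
        raise ValidationError("nothing to aggregate")
    df = rows.copy()
    if "grouping" not in df.columns:
        df["grouping"] = "all"

    def agg(group: pd.DataFrame) -> pd.Series:
        res = {"n_countries": len(group)}
        pop = group["pop_u5"].to_numpy(dtype=float) if "pop_u5" in group else None
        for col in ("shock", "prev2019", "prev2021"):
            if col in group:
                vals = group[col].to_numpy(dtype=float)
                res[col] = (
                    float(np.average(vals, weights=pop))
                    if pop is not None
                    else float(vals.mean())
                )
        for col in ("wasted2019", "wasted2021", "change"):
            if col in group:
                res[col] = float(group[col].sum())
        return pd.Series(res)

    regional = (
        df.groupby("grouping", sort=True).apply(agg, include_groups=False).reset_index()
    )
    total = agg(df)
    total["grouping"] = "Total"
    return pd.concat([regional, pd.DataFrame([total])], ignore_index=True)
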