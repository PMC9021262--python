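"""Wasting classification, weighted prevalence, bands, and age profiles."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "classify_wasting",
    "weighted_prevalence",
    "prevalence_band",
    "age_profile",
    "WASTING_CUTOFFS",
    "PREVALENCE_BANDS",
]

logger = logging.getLogger(__name__)

#: Strict z-score cutoffs for the three severity levels.
WASTING_CUTOFFS = {"wasting_any": -1.0, "wasting_mod_sev": -2.0, "wasting_severe": -3.0}

#: Half-open prevalence bands in percent: [0,5) [5,10) [10,15) [15,100].
PREVALENCE_BANDS = (
    (0.0, 5.0, "low/very low"),
    (5.0, 10.0, "medium"),
    (10.0, 15.0, "high"),
    (15.0, 100.0, "very high"),
)

#: Plausibility filter on |WHZ|; records outside are excluded, not clipped.
DEFAULT_WHZ_LIMIT = 5.0


def classify_wasting(
    whz, whz_limit: float = DEFAULT_WHZ_LIMIT
) -> pd.DataFrame:
    """Binary indicators from weight-for-height z-scores, strict cutoffs.

    Non-finite values and values with |WHZ| > ``whz_limit`` are flagged:
    their indicator rows are NaN and the exclusion count is logged. The
    indicators nest (severe implies moderate/severe implies any) by
    construction.
    """
    z = np.asarray(whz, dtype=float)
    valid = np.isfinite(z) & (np.abs(z) <= whz_limit)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning(
            "classify_wasting: excluded %d records (non-finite or |WHZ| > %g)",
            n_excluded,
            whz_limit,
        )
    out = pd.DataFrame(index=pd.RangeIndex(len(z)))
    for col, cutoff in WASTING_CUTOFFS.items():
        ind = np.where(valid, (z < cutoff).astype(float), np.nan)
        out[col] = ind
    return out


def weighted_prevalence(y, w=None) -> float:
    """Weighted prevalence in percent: 100 * sum(w*y) / sum(w)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValidationError("weighted_prevalence: empty selection")
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    if (w <= 0).any():
        raise ValidationError("weights must be positive")
    return float(100.0 * np.sum(w * y) / np.sum(w))


def prevalence_band(prev: float) -> str:
    """Band label for a percent prevalence; bands are half-open except the top."""
    if not np.isfinite(prev) or prev < 0.0 or prev > 100.0:
        raise ValidationError(f"prevalence {prev!r} outside [0, 100]")
    for lo, hi, label in PREVALENCE_BANDS:
        if lo <= prev < hi:
            return label
    return PREVALENCE_BANDS[-1][2]  # prev == 100.0


def age_profile(
    children: pd.DataFrame,
    indicator: str,
    weight_col: str | None = "design_weight",
    bandwidth_months: int = 3,
) -> pd.DataFrame:
    """Kernel-smoothed prevalence by integer age (0-59), per region.

    A triangular kernel of half-width ``bandwidth_months`` is applied to the
    per-age weighted prevalences; bandwidth 0 returns the raw per-age values.
    Regions without children are omitted with a warning. Returns a tidy frame
    (region, age_months, prevalence, n).
    """
    if bandwidth_months < 0:
        raise ValidationError("bandwidth_months must be >= 0")
    if indicator not in children.columns:
        raise ValidationError(f"indicator column {indicator!r} not found")
    df = children.dropna(subset=[indicator])
    if df.empty:
        raise ValidationError("no usable children for age profile")
    w = (
        df[weight_col].to_numpy(dtype=float)
        if weight_col is not None
        else np.ones(len(df))
    )
    ages = np.arange(60)
    rows = []
    for region, grp_idx in df.groupby("region").groups.items():
        grp = df.loc[grp_idx]
        gw = w[df.index.get_indexer(grp_idx)]
        num = np.zeros(60)
        den = np.zeros(60)
        counts = np.zeros(60, dtype=int)
        a = grp["age_months"].to_numpy()
        y = grp[indicator].to_numpy(dtype=float)
        np.add.at(num, a, gw * y)
        np.add.at(den, a, gw)
        np.add.at(counts, a, 1)
        # Triangular kernel over neighbouring integer ages.
        half = bandwidth_months
        kern = np.array([1.0 - abs(d) / (half + 1.0) for d in range(-half, half + 1)])
        offsets = np.arange(-half, half + 1)
        sm_num = np.zeros(60)
        sm_den = np.zeros(60)
        for k, d in zip(kern, offsets):
            src = np.clip(ages + d, 0, None)
            ok = (ages + d >= 0) & (ages + d < 60)
            sm_num[ok] += k * num[(ages + d)[ok]]
            sm_den[ok] += k * den[(ages + d)[ok]]
        with np.errstate(invalid="ignore", divide="ignore"):
            prev = 100.0 * sm_num / sm_den
        for age in ages:
            if sm_den[age] > 0:
                rows.append(
                    {
                        "region": region,
                        "age_months": int(age),
                        "prevalence": float(prev[age]),
                        "n": int(counts[age]),
                    }
                )
    present = {r["region"] for r in rows}
    for region in children["region"].unique():
        if region not in present:
            logger.warning("age_profile: region %r has no usable children", region)
    return pd.DataFrame(rows)
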