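"""Three-step reweighting for pooled multi-country survey regressions.

Step 1 scales each country to its share of the pooled under-5 population,
step 2 equalizes round totals within a country, step 3 applies the survey
design weights. The composite is the product of the three, rescaled so
weights sum to the number of child records — a pure convention, since every
weighted-least-squares point estimate is invariant to rescaling.
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

__all__ = [
    "country_population_factors",
    "round_balance_factors",
    "composite_weights",
    "attach_weights",
    "weights_audit",
]


def country_population_factors(
    meta: pd.DataFrame, sample_sizes: pd.Series
) -> pd.Series:
    """Per-country factor: population share divided by sample share.

    After weighting, each country's total weight share equals its share of
    the pooled under-5 population.
    """
    if sample_sizes.empty:
        raise ValidationError("no countries in sample_sizes")
    pops = meta.set_index("country")["pop_u5"]
    missing = sample_sizes.index.difference(pops.index)
    if len(missing):
        raise ValidationError(f"countries missing from meta: {list(missing)}")
    pops = pops.loc[sample_sizes.index]
    bad = pops[pops <= 0]
    if len(bad):
        raise ValidationError(
            f"non-positive under-5 population for: {list(bad.index)}"
        )
    if (sample_sizes <= 0).any():
        empty = list(sample_sizes.index[sample_sizes <= 0])
        raise ValidationError(f"empty or negative sample for: {empty}")
    pop_share = pops / pops.sum()
    sample_share = sample_sizes / sample_sizes.sum()
    return (pop_share / sample_share).rename("step1_country_factor")


def round_balance_factors(children: pd.DataFrame) -> pd.Series:
    """Per-(country, round) factor: mean round size / round size.

    Gives every round of a country equal total weight regardless of how
    unbalanced the sample sizes are.
    """
    if children.empty:
        raise ValidationError("children table is empty")
    sizes = children.groupby(["country", "round_id"]).size()
    if (sizes == 0).any():
        raise ValidationError("empty round encountered")
    mean_size = sizes.groupby("country").transform("mean")
    return (mean_size / sizes).rename("step2_round_factor")


def composite_weights(children: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-child weight set: the three factors plus the rescaled composite.

    Returns a frame aligned to ``children.index`` with columns
    ``step1_country_factor``, ``step2_round_factor``, ``step3_design_weight``
    and ``composite_weight`` (sums to the number of records).
    """
    if (children["design_weight"] <= 0).any():
        n_bad = int((children["design_weight"] <= 0).sum())
        raise ValidationError(f"{n_bad} non-positive design weights")
    step1_by_country = country_population_factors(
        meta, children.groupby("country").size()
    )
    step2_by_round = round_balance_factors(children)

    out = pd.DataFrame(index=children.index)
    out["step1_country_factor"] = children["country"].map(step1_by_country)
    key = pd.MultiIndex.from_arrays([children["country"], children["round_id"]])
    out["step2_round_factor"] = key.map(step2_by_round).to_numpy()
    out["step3_design_weight"] = children["design_weight"].to_numpy()
    raw = (
        out["step1_country_factor"]
        * out["step2_round_factor"]
        * out["step3_design_weight"]
    )
    out["composite_weight"] = raw * (len(children) / raw.sum())
    return out


def attach_weights(children: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Copy of ``children`` with a ``composite_weight`` column attached."""
    out = children.copy()
    out["composite_weight"] = composite_weights(children, meta)["composite_weight"]
    return out


def weights_audit(children: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Per country/round totals and shares for eyeballing the scheme."""
    df = pd.DataFrame(
        {
            "country": children["country"],
            "round_id": children["round_id"],
            "w": weights["composite_weight"],
        }
    )
    audit = df.groupby(["country", "round_id"])["w"].agg(total="sum", n="count")
    audit["share"] = audit["total"] / audit["total"].sum()
    return audit.reset_index()
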