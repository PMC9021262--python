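"""Seeded multi-country survey + macro data generator with a planted elasticity.

The generator produces the three tables the estimation pipeline consumes
(children, macro levels, country metadata) from a single :class:`SimConfig`.
The conditional mean of every wasting indicator is exactly linear in the
estimating equation's regressors, so the downstream weighted least squares
estimator — when supplied the true long-run prevalences — is unbiased for the
planted elasticity ``beta_true``. This is the property that makes parameter
recovery and confidence-interval coverage testable without restricted survey
microdata.

Randomness is split into independent sub-streams (macro, children,
mechanisms) derived from the single global seed, so adding or re-running one
stage never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .macro import annual_growth

__all__ = [
    "DEFAULT_REGIONS",
    "SimConfig",
    "SyntheticDataset",
    "generate_macro",
    "generate_children",
    "generate_mechanism_outcomes",
    "generate_dataset",
]

#: Ten region groupings used for region-specific temporal effects.
DEFAULT_REGIONS: tuple[str, ...] = (
    "Sahel & Horn",
    "Western & Central Africa",
    "Eastern & Southern Africa",
    "South Asia",
    "South-East Asia",
    "Middle East",
    "North Africa",
    "Eastern Europe",
    "Central Asia",
    "Latin America & Caribbean",
)

# Sub-stream identifiers appended to the global seed.
_STREAM_MACRO = 0
_STREAM_CHILDREN = 1
_STREAM_MECHANISMS = 2

#: Default planted contemporaneous elasticities for the mechanism outcomes
#: (minimum diet diversity responds positively to growth, the rest negatively).
DEFAULT_MECH_ELASTICITIES: Mapping[str, float] = {
    "diarrhea": -0.10,
    "fever_only": -0.08,
    "low_mbmi": -0.06,
    "mdd": 0.19,
}

DEFAULT_MECH_BASELINE_RANGES: Mapping[str, tuple[float, float]] = {
    "diarrhea": (0.10, 0.22),
    "fever_only": (0.10, 0.25),
    "low_mbmi": (0.05, 0.20),
    "mdd": (0.20, 0.40),
}

#: Marginal rates for the binary household/maternal covariates.
_COVARIATE_RATES: Mapping[str, float] = {
    "piped_water": 0.40,
    "flush_toilet": 0.25,
    "facility_birth": 0.50,
    "anc4": 0.45,
    "fully_vaccinated": 0.55,
    "teen_birth": 0.20,
    "parity_4plus": 0.35,
    "female": 0.49,
    "rural": 0.65,
}

MDD_AGE_RANGE = (6, 35)


@dataclass(frozen=True)
class SimConfig:
    """Configuration for one synthetic dataset.

    Growth quantities are annual fractions (0.02 = 2% per year);
    ``beta_true`` is the elasticity per 10% growth change, matching the
    unit of the estimated coefficient.
    """

    n_countries: int = 40
    regions: tuple[str, ...] = DEFAULT_REGIONS
    year_start: int = 1990
    year_end: int = 2018
    rounds_min: int = 2
    rounds_max: int = 4
    children_per_round: int = 2000
    beta_true: float = -0.15
    baseline_prev_range: tuple[float, float] = (0.03, 0.25)
    any_wasting_ratio: float = 2.0
    severe_wasting_ratio: float = 0.35
    growth_trend_mean: float = 0.02
    growth_trend_sd: float = 0.01
    growth_shock_sd: float = 0.05
    gni_gdp_corr: float = 0.90
    shock_measure: str = "gni"
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "asset_some": -0.003,
            "asset_all": -0.006,
            "maternal_education_years": -0.0003,
            "rural": 0.003,
        }
    )
    asset_shares: tuple[float, float, float] = (0.34, 0.59, 0.07)
    age_effect_amplitude: float = 0.02
    age_effect_peak: float = 11.0
    season_amplitude: float = 0.003
    trend_effect_sd: float = 0.003
    round_size_multiplier_range: tuple[float, float] = (0.25, 4.0)
    design_weight_sigma: float = 0.3
    clamp_bounds: tuple[float, float] = (0.001, 0.999)
    max_clamp_frac: float = 0.01
    mech_elasticities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MECH_ELASTICITIES)
    )
    mech_baseline_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MECH_BASELINE_RANGES)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_countries < 1:
            raise ValidationError("n_countries must be >= 1")
        if not self.regions:
            raise ValidationError("regions roster must be non-empty")
        if self.year_end <= self.year_start:
            raise ValidationError("year span must be non-degenerate")
        if not (1 <= self.rounds_min <= self.rounds_max):
            raise ValidationError("rounds range must satisfy 1 <= min <= max")
        if self.children_per_round < 1:
            raise ValidationError("children_per_round must be >= 1")
        lo, hi = self.baseline_prev_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("baseline_prev_range must be a sub-interval of (0, 1)")
        if not np.isfinite(self.beta_true):
            raise ValidationError("beta_true must be finite")
        if abs(self.gni_gdp_corr) > 1.0:
            raise ValidationError("gni_gdp_corr must lie in [-1, 1]")
        if self.gni_gdp_corr <= 0.0:
            # Additive-noise calibration only reaches positive correlations.
            raise ValidationError(
                "gni_gdp_corr must be positive for the additive-noise calibration"
            )
        if self.shock_measure not in ("gni", "gdp"):
            raise ValidationError("shock_measure must be 'gni' or 'gdp'")
        if abs(sum(self.asset_shares) - 1.0) > 1e-9 or min(self.asset_shares) < 0:
            raise ValidationError("asset_shares must be a probability vector")
        mlo, mhi = self.round_size_multiplier_range
        if not (0.0 < mlo <= mhi):
            raise ValidationError("round_size_multiplier_range must be positive")
        clo, chi = self.clamp_bounds
        if not (0.0 <= clo < chi <= 1.0):
            raise ValidationError("clamp_bounds must satisfy 0 <= lo < hi <= 1")
        n_years = self.year_end - (self.year_start + 2) + 1
        if n_years < self.rounds_max:
            raise ValidationError(
                "year span too short for rounds_max distinct interview years"
            )

    def country_codes(self) -> list[str]:
        return [f"C{i:03d}" for i in range(self.n_countries)]

    def country_regions(self) -> dict[str, str]:
        """Deterministic round-robin region assignment (no RNG involved)."""
        return {
            code: self.regions[i % len(self.regions)]
            for i, code in enumerate(self.country_codes())
        }


@dataclass
class SyntheticDataset:
    """Children table, macro levels, country metadata and planted truth."""

    children: pd.DataFrame
    macro: pd.DataFrame
    meta: pd.DataFrame
    truth: dict

    def validate(self) -> None:
        growth_years = set(
            zip(self.macro["country"], self.macro["year"])
        )
        need = set(
            zip(self.children["country"], self.children["interview_year"] - 1)
        )
        missing = need - growth_years
        if missing:
            raise ValidationError(
                f"macro series missing (country, year-1) pairs: {sorted(missing)[:5]}"
            )
        if not set(self.children["country"]) <= set(self.meta["country"]):
            raise ValidationError("children reference countries absent from meta")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def generate_macro(cfg: SimConfig) -> pd.DataFrame:
    """Simulate per-capita GDP and GNI levels for each country-year.

    GDP levels compound country trend growth plus annual i.i.d. deviations;
    GNI growth adds independent noise calibrated so the pooled correlation of
    the two growth series equals ``gni_gdp_corr`` (noise variance
    sigma_tot^2 * (1/rho^2 - 1) added to a series of variance sigma_tot^2
    yields correlation rho).

    Returns a tidy frame with columns country, year, gdp_pc, gni_pc.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_MACRO)
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    n_years = len(years)
    codes = cfg.country_codes()

    mu = rng.normal(cfg.growth_trend_mean, cfg.growth_trend_sd, size=cfg.n_countries)
    eps = rng.normal(0.0, cfg.growth_shock_sd, size=(cfg.n_countries, n_years - 1))
    gdp_growth = mu[:, None] + eps

    rho = cfg.gni_gdp_corr
    sigma_tot = float(np.hypot(cfg.growth_shock_sd, cfg.growth_trend_sd))
    noise_sd = sigma_tot * np.sqrt(max(1.0 / rho**2 - 1.0, 0.0))
    gni_growth = gdp_growth + rng.normal(0.0, noise_sd, size=gdp_growth.shape)

    # Keep levels strictly positive even under pathological configs.
    gdp_growth = np.clip(gdp_growth, -0.9, None)
    gni_growth = np.clip(gni_growth, -0.9, None)

    gdp0 = np.exp(rng.normal(np.log(2000.0), 0.7, size=cfg.n_countries))
    gni0 = gdp0 * rng.uniform(0.85, 1.25, size=cfg.n_countries)

    gdp = np.empty((cfg.n_countries, n_years))
    gni = np.empty((cfg.n_countries, n_years))
    gdp[:, 0] = gdp0
    gni[:, 0] = gni0
    for t in range(1, n_years):
        gdp[:, t] = gdp[:, t - 1] * (1.0 + gdp_growth[:, t - 1])
        gni[:, t] = gni[:, t - 1] * (1.0 + gni_growth[:, t - 1])

    return pd.DataFrame(
        {
            "country": np.repeat(codes, n_years),
            "year": np.tile(years, cfg.n_countries),
            "gdp_pc": gdp.ravel(),
            "gni_pc": gni.ravel(),
        }
    )


def _growth_lookup(macro: pd.DataFrame, measure: str) -> pd.Series:
    growth = annual_growth(macro, measure)
    return growth.set_index(["country", "year"])["growth"]


def _age_effect(cfg: SimConfig, age: np.ndarray) -> np.ndarray:
    return cfg.age_effect_amplitude * np.exp(
        -0.5 * ((age - cfg.age_effect_peak) / 8.0) ** 2
    )


def generate_children(cfg: SimConfig, macro: pd.DataFrame) -> SyntheticDataset:
    """Draw child records whose wasting indicators embed ``beta_true``.

    Each indicator k with country baseline p_k is Bernoulli with

        p = clamp(p_k * (1 + beta_true * g / 10) + delta_age + delta_month
                  + delta_trend + gamma'X, lo, hi)

    where g is percent growth of ``shock_measure`` in the year before the
    interview. A single uniform draw is shared across the three indicators so
    severe <= moderate/severe <= any nesting holds record by record while
    each indicator keeps its own marginal probability.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_CHILDREN)
    codes = cfg.country_codes()
    region_of = cfg.country_regions()
    growth = _growth_lookup(macro, cfg.shock_measure)

    # Country-level planted parameters.
    lo, hi = cfg.baseline_prev_range
    p_mod = rng.uniform(lo, hi, size=cfg.n_countries)
    p_any = np.minimum(p_mod * cfg.any_wasting_ratio, 0.60)
    p_sev = p_mod * cfg.severe_wasting_ratio
    pop_u5 = np.exp(rng.normal(np.log(2e6), 1.0, size=cfg.n_countries))

    # Region-level nuisance effects (seasonality phase, secular trend shifts).
    phases = {r: rng.integers(0, 12) for r in cfg.regions}
    n_brackets = (cfg.year_end - 1990) // 5 + 2
    trend_shift = {
        (r, b): rng.normal(0.0, cfg.trend_effect_sd)
        for r in cfg.regions
        for b in range(-8, n_brackets)
    }

    feasible_years = np.arange(cfg.year_start + 2, cfg.year_end + 1)
    mlo, mhi = cfg.round_size_multiplier_range

    frames = []
    for ci, code in enumerate(codes):
        n_rounds = int(rng.integers(cfg.rounds_min, cfg.rounds_max + 1))
        round_years = np.sort(
            rng.choice(feasible_years, size=n_rounds, replace=False)
        )
        for ri, year in enumerate(round_years):
            mult = np.exp(rng.uniform(np.log(mlo), np.log(mhi)))
            size = max(1, int(round(cfg.children_per_round * mult)))
            frames.append(
                pd.DataFrame(
                    {
                        "country": code,
                        "region": region_of[code],
                        "round_id": f"{code}-r{ri + 1}",
                        "interview_year": int(year),
                        "interview_month": rng.integers(1, 13, size=size),
                        "age_months": rng.integers(0, 60, size=size),
                    }
                )
            )
    children = pd.concat(frames, ignore_index=True)
    n = len(children)

    # Household / maternal covariates.
    asset = rng.choice(np.array(["none", "some", "all"]), size=n, p=cfg.asset_shares)
    children["asset_class"] = asset
    children["maternal_education_years"] = np.clip(rng.poisson(4.0, size=n), 0, 18)
    for col, rate in _COVARIATE_RATES.items():
        children[col] = (rng.random(n) < rate).astype(np.int8)
    sigma = cfg.design_weight_sigma
    children["design_weight"] = rng.lognormal(-0.5 * sigma**2, sigma, size=n)

    # Linear predictor pieces shared across the three indicators.
    g_pct = (
        pd.MultiIndex.from_arrays(
            [children["country"], children["interview_year"] - 1]
        )
        .map(growth)
        .to_numpy(dtype=float)
    )
    if np.isnan(g_pct).any():
        raise ValidationError("macro series does not cover interview_year - 1")

    shift = _age_effect(cfg, children["age_months"].to_numpy(dtype=float))
    phase = children["region"].map(phases).to_numpy(dtype=float)
    shift = shift + cfg.season_amplitude * np.sin(
        2.0 * np.pi * (children["interview_month"].to_numpy() - phase) / 12.0
    )
    brackets = (children["interview_year"].to_numpy() - 1990) // 5
    shift = shift + np.array(
        [trend_shift[(r, b)] for r, b in zip(children["region"], brackets)]
    )
    gamma = dict(cfg.covariate_effects)
    xcols = pd.DataFrame(
        {
            "asset_some": (asset == "some").astype(float),
            "asset_all": (asset == "all").astype(float),
        }
    )
    for col, eff in gamma.items():
        vals = (
            xcols[col].to_numpy()
            if col in xcols
            else children[col].to_numpy(dtype=float)
        )
        shift = shift + eff * vals

    scale = 1.0 + cfg.beta_true * g_pct / 10.0
    idx = children["country"].map({c: i for i, c in enumerate(codes)}).to_numpy()
    clo, chi = cfg.clamp_bounds
    clamped = np.zeros(n, dtype=bool)
    probs = {}
    # Nuisance shifts scale with the indicator's severity ratio so rare
    # (severe) outcomes are not swamped by additive effects sized for the
    # moderate baseline; per-indicator linearity in the design is preserved
    # because the factor is a global constant.
    shift_scale = {
        "any": cfg.any_wasting_ratio,
        "mod_sev": 1.0,
        "severe": cfg.severe_wasting_ratio,
    }
    for name, base in (("any", p_any), ("mod_sev", p_mod), ("severe", p_sev)):
        raw = base[idx] * scale + shift_scale[name] * shift
        clamped |= (raw < clo) | (raw > chi)
        probs[name] = np.clip(raw, clo, chi)
    clamp_frac = float(clamped.mean())
    if clamp_frac > cfg.max_clamp_frac:
        raise ValidationError(
            f"probability clamping hit {clamp_frac:.1%} of children "
            f"(limit {cfg.max_clamp_frac:.1%}); config is inconsistent"
        )

    u = rng.random(n)
    children["wasting_any"] = (u < probs["any"]).astype(np.int8)
    children["wasting_mod_sev"] = (u < probs["mod_sev"]).astype(np.int8)
    children["wasting_severe"] = (u < probs["severe"]).astype(np.int8)

    meta = pd.DataFrame(
        {
            "country": codes,
            "region": [region_of[c] for c in codes],
            "pop_u5": pop_u5,
            "mean_prev_any": p_any * 100.0,
            "mean_prev_mod_sev": p_mod * 100.0,
            "mean_prev_severe": p_sev * 100.0,
        }
    )

    truth = {
        "seed": cfg.seed,
        "beta_true": cfg.beta_true,
        "shock_measure": cfg.shock_measure,
        "baseline_prev": {
            code: {
                "any": float(p_any[i]),
                "mod_sev": float(p_mod[i]),
                "severe": float(p_sev[i]),
            }
            for i, code in enumerate(codes)
        },
        "covariate_effects": gamma,
        "clamp_frac": clamp_frac,
    }
    ds = SyntheticDataset(children=children, macro=macro, meta=meta, truth=truth)
    ds.validate()
    return ds


def generate_mechanism_outcomes(cfg: SimConfig, ds: SyntheticDataset) -> SyntheticDataset:
    """Add morbidity / maternal-nutrition / diet columns with planted
    contemporaneous-shock elasticities.

    Minimum diet diversity (``mdd``) is generated only for children aged
    6-35 months and is missing otherwise.
    """
    cfg.validate()
    if ds.children.empty:
        raise ValidationError("dataset has no children")
    rng = _rng(cfg, _STREAM_MECHANISMS)
    children = ds.children.copy()
    meta = ds.meta.copy()
    growth = _growth_lookup(ds.macro, cfg.shock_measure)
    g0 = (
        pd.MultiIndex.from_arrays([children["country"], children["interview_year"]])
        .map(growth)
        .to_numpy(dtype=float)
    )
    if np.isnan(g0).any():
        raise ValidationError("macro series does not cover contemporaneous years")

    codes = meta["country"].tolist()
    idx = children["country"].map({c: i for i, c in enumerate(codes)}).to_numpy()
    clo, chi = cfg.clamp_bounds
    n = len(children)
    baselines: dict[str, np.ndarray] = {}
    for name, beta in cfg.mech_elasticities.items():
        blo, bhi = cfg.mech_baseline_ranges[name]
        base = rng.uniform(blo, bhi, size=len(codes))
        baselines[name] = base
        p = np.clip(base[idx] * (1.0 + beta * g0 / 10.0), clo, chi)
        draw = (rng.random(n) < p).astype(float)
        if name == "mdd":
            lo_m, hi_m = MDD_AGE_RANGE
            eligible = children["age_months"].between(lo_m, hi_m)
            draw = np.where(eligible, draw, np.nan)
        children[name] = draw
        meta[f"mean_prev_{name}"] = base * 100.0

    truth = dict(ds.truth)
    truth["mech_elasticities"] = dict(cfg.mech_elasticities)
    truth["mech_baseline_prev"] = {
        name: {code: float(base[i]) for i, code in enumerate(codes)}
        for name, base in baselines.items()
    }
    return SyntheticDataset(children=children, macro=ds.macro, meta=meta, truth=truth)


def generate_dataset(cfg: SimConfig, mechanisms: bool = False) -> SyntheticDataset:
    """Convenience wrapper: macro -> children -> (optional) mechanisms."""
    macro = generate_macro(cfg)
    ds = generate_children(cfg, macro)
    if mechanisms:
        ds = generate_mechanism_outcomes(cfg, ds)
    return ds


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of ``cfg`` with a different global seed."""
    return replace(cfg, seed=seed)
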