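"""Weighted linear probability model with fixed effects and clustered errors.

The estimating equation regresses a binary child outcome on the
shock x long-run-prevalence interaction plus household controls, country
fixed effects and region-specific temporal effects (age-in-months, interview
month, 5-year bracket), weighted by the three-step composite weights.
Inference uses the cluster-robust sandwich over country-level score sums
with a CR1 small-sample factor and t(G-1) critical values.

The coefficient on the interaction is an elasticity: percent change in
prevalence per 10% change in per-capita income.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import macro as macro_mod
from . import weighting
from .errors import EstimationError, ValidationError

__all__ = [
    "ModelSpec",
    "Design",
    "FitResult",
    "build_design",
    "fit_wls",
    "estimate_elasticity",
    "estimate_mechanism",
    "estimate_subgroup",
]

logger = logging.getLogger(__name__)

WASTING_OUTCOMES = ("any", "mod_sev", "severe")
MECHANISM_OUTCOMES = ("diarrhea", "fever_only", "low_mbmi", "mdd")

#: Binary household / maternal controls entered directly.
DHS_BINARY_CONTROLS = (
    "piped_water",
    "flush_toilet",
    "facility_birth",
    "anc4",
    "fully_vaccinated",
    "teen_birth",
    "parity_4plus",
    "female",
    "rural",
)

_BRACKET_ANCHOR = 1990  # 5-year brackets: 1990-94, 1995-99, ...

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """What to regress and how."""

    outcome: str = "mod_sev"
    measure: str = "gni"
    lag: int = 1
    dhs_controls: bool = True
    country_fe: bool = True
    region_age: bool = True
    region_month: bool = True
    region_bracket: bool = True
    subgroup_interactions: tuple[str, ...] = ()
    extra_controls: tuple[str, ...] = ()
    growth_trim: tuple[float, float] | None = None
    mean_prev_source: str = "data"  # "data" or "meta"
    small_sample: str = "CR1"  # "CR1" or "none"
    ci_level: float = 0.95

    def validate(self) -> None:
        if self.outcome not in WASTING_OUTCOMES + MECHANISM_OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.measure not in macro_mod.MEASURES:
            raise ValidationError(f"measure must be one of {macro_mod.MEASURES}")
        for sg in self.subgroup_interactions:
            if sg not in ("urban", "girl"):
                raise ValidationError(f"unknown subgroup {sg!r}")
        if self.mean_prev_source not in ("data", "meta"):
            raise ValidationError("mean_prev_source must be 'data' or 'meta'")
        if self.small_sample not in ("CR1", "none"):
            raise ValidationError("small_sample must be 'CR1' or 'none'")
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError("ci_level must be in (0, 1)")
        if self.growth_trim is not None:
            lo, hi = self.growth_trim
            if not (0.0 <= lo < hi <= 100.0):
                raise ValidationError("growth_trim must be percentiles lo < hi")


def outcome_column(outcome: str) -> str:
    if outcome in WASTING_OUTCOMES:
        return f"wasting_{outcome}"
    return outcome


@dataclass
class Design:
    """Assembled design matrix plus bookkeeping from row/column drops."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    w: np.ndarray
    clusters: np.ndarray
    dropped_columns: list[str]
    n_dropped_rows: int
    reference_levels: dict[str, str]


@dataclass
class FitResult:
    """Point estimates, clustered covariance, and fit metadata."""

    params: pd.Series
    se: pd.Series
    ci_lo: pd.Series
    ci_hi: pd.Series
    vcov: pd.DataFrame
    r2: float
    n_obs: int
    n_clusters: int
    df: int
    dropped_columns: list[str] = field(default_factory=list)
    n_dropped_rows: int = 0
    reference_levels: dict[str, str] = field(default_factory=dict)
    spec: ModelSpec | None = None

    @property
    def beta_g(self) -> float:
        """The elasticity: coefficient on the shock interaction."""
        return float(self.params["shock"])

    def ci(self, term: str = "shock") -> tuple[float, float]:
        return float(self.ci_lo[term]), float(self.ci_hi[term])

    def summary(self) -> pd.DataFrame:
        """Tidy per-term table (term, estimate, se_clustered, ci_lo, ci_hi, block)."""

        def block(term: str) -> str:
            if term == "intercept":
                return "intercept"
            if term.startswith("shock"):
                return "shock"
            if term.startswith("country="):
                return "country_fe"
            if term.startswith(("region_age", "region_month", "region_bracket")):
                return "temporal"
            return "controls"

        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se_clustered": self.se.to_numpy(),
                "ci_lo": self.ci_lo.to_numpy(),
                "ci_hi": self.ci_hi.to_numpy(),
                "block": [block(t) for t in self.params.index],
            }
        )


def _dummies(labels: pd.Series, prefix: str, reference_levels: dict[str, str]) -> pd.DataFrame:
    """Indicator columns for every level except the lexicographically first."""
    levels = sorted(labels.unique())
    reference_levels[prefix] = levels[0]
    cols = {}
    arr = labels.to_numpy()
    for lev in levels[1:]:
        cols[f"{prefix}={lev}"] = (arr == lev).astype(float)
    return pd.DataFrame(cols, index=labels.index)


def build_design(
    children: pd.DataFrame,
    meta: pd.DataFrame,
    macro: pd.DataFrame,
    spec: ModelSpec,
    mean_prev: pd.Series | None = None,
) -> Design:
    """Assemble outcome, regressors, composite weights and cluster ids.

    ``mean_prev`` (percent per country) overrides the spec's source — used to
    supply true long-run prevalences in simulation studies. Rows with any
    missing required field are dropped and counted; exactly collinear columns
    are pruned with their names recorded. If the shock column itself is
    unidentified after pruning, estimation cannot proceed and an
    :class:`EstimationError` is raised.
    """
    spec.validate()
    ycol = outcome_column(spec.outcome)
    if ycol not in children.columns:
        raise ValidationError(f"outcome column {ycol!r} not in children table")
    df = children
    if "composite_weight" not in df.columns:
        df = weighting.attach_weights(df, meta)

    if spec.outcome == "mdd":
        from .simulate import MDD_AGE_RANGE

        lo_m, hi_m = MDD_AGE_RANGE
        df = df[df["age_months"].between(lo_m, hi_m)]

    if mean_prev is None:
        if spec.mean_prev_source == "meta":
            col = f"mean_prev_{spec.outcome}"
            if col not in meta.columns:
                raise ValidationError(f"meta lacks column {col!r}")
            mean_prev = meta.set_index("country")[col]
        else:
            mean_prev = macro_mod.long_run_mean_prevalence(df, ycol)

    shock = macro_mod.shock_regressor(df, macro, mean_prev, spec.measure, spec.lag)

    if spec.growth_trim is not None:
        growth = macro_mod.annual_growth(macro, spec.measure).set_index(
            ["country", "year"]
        )["growth"]
        g = (
            pd.MultiIndex.from_arrays([df["country"], df["interview_year"] - spec.lag])
            .map(growth)
            .to_numpy(dtype=float)
        )
        cy = pd.DataFrame(
            {"country": df["country"], "year": df["interview_year"] - spec.lag, "g": g}
        ).drop_duplicates()
        lo, hi = np.nanpercentile(cy["g"], spec.growth_trim)
        keep = (g >= lo) & (g <= hi)
        df = df[keep]
        shock = shock[keep]

    reference_levels: dict[str, str] = {}
    blocks: list[pd.DataFrame] = []
    blocks.append(pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index))
    blocks.append(shock.rename("shock").to_frame())

    if spec.subgroup_interactions:
        sub = {}
        if "urban" in spec.subgroup_interactions:
            urban = 1.0 - df["rural"].to_numpy(dtype=float)
            if np.ptp(urban) == 0:
                logger.warning("urban indicator constant; interaction dropped")
            else:
                sub["urban"] = urban
                sub["shock_x_urban"] = shock.to_numpy() * urban
        if "girl" in spec.subgroup_interactions:
            girl = df["female"].to_numpy(dtype=float)
            if np.ptp(girl) == 0:
                logger.warning("girl indicator constant; interaction dropped")
            else:
                sub["shock_x_girl"] = shock.to_numpy() * girl
        if sub:
            blocks.append(pd.DataFrame(sub, index=df.index))

    if spec.dhs_controls:
        ctl = _dummies(df["asset_class"], "asset", reference_levels)
        # Canonical reference is "no assets"; lexicographic order of
        # {all, none, some} would pick "all", so force it.
        if "asset=none" in ctl.columns:
            ctl = ctl.drop(columns=["asset=none"])
            ctl["asset=all"] = (df["asset_class"] == "all").astype(float)
            ctl["asset=some"] = (df["asset_class"] == "some").astype(float)
            reference_levels["asset"] = "none"
        ctl["maternal_education_years"] = df["maternal_education_years"].astype(float)
        for col in DHS_BINARY_CONTROLS:
            ctl[col] = df[col].astype(float)
        blocks.append(ctl)

    if spec.country_fe and df["country"].nunique() > 1:
        blocks.append(_dummies(df["country"], "country", reference_levels))

    if spec.region_age:
        lab = df["region"].astype(str) + "|a" + df["age_months"].map("{:02d}".format)
        blocks.append(_dummies(lab, "region_age", reference_levels))
    if spec.region_month:
        lab = df["region"].astype(str) + "|m" + df["interview_month"].map(
            "{:02d}".format
        )
        blocks.append(_dummies(lab, "region_month", reference_levels))
    if spec.region_bracket:
        start = (
            (df["interview_year"] - _BRACKET_ANCHOR) // 5 * 5 + _BRACKET_ANCHOR
        )
        lab = df["region"].astype(str) + "|t" + start.astype(str)
        blocks.append(_dummies(lab, "region_bracket", reference_levels))

    for col in spec.extra_controls:
        if col not in df.columns:
            raise ValidationError(f"extra control column {col!r} not found")
        blocks.append(df[col].astype(float).rename(col).to_frame())

    Xdf = pd.concat(blocks, axis=1)
    used = pd.concat(
        [df[ycol].astype(float), df["composite_weight"], Xdf], axis=1
    )
    ok = ~used.isna().any(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("build_design: dropped %d rows with missing fields", n_dropped)
    Xdf = Xdf.loc[ok]
    y = df.loc[ok, ycol].to_numpy(dtype=float)
    w = df.loc[ok, "composite_weight"].to_numpy(dtype=float)
    clusters = df.loc[ok, "country"].to_numpy()
    if len(Xdf) == 0:
        raise ValidationError("no rows left after listwise deletion")

    X = Xdf.to_numpy(dtype=float)
    columns = list(Xdf.columns)
    X, columns, dropped_cols = _prune_collinear(
        X, columns, w, protected=("intercept", "shock")
    )
    if dropped_cols:
        logger.info("build_design: pruned collinear columns: %s", dropped_cols)
    return Design(
        X=X,
        columns=columns,
        y=y,
        w=w,
        clusters=clusters,
        dropped_columns=dropped_cols,
        n_dropped_rows=n_dropped,
        reference_levels=reference_levels,
    )


def _prune_collinear(
    X: np.ndarray,
    columns: list[str],
    w: np.ndarray,
    protected: tuple[str, ...] = (),
) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop exactly collinear columns, keeping earlier columns over later.

    Protected columns are ordered first so the shock regressor is never
    sacrificed to a redundant dummy; if a protected column is itself
    dependent on the others the design cannot identify it and a hard error
    is raised.
    """
    order = sorted(
        range(len(columns)),
        key=lambda j: (columns[j] not in protected, j),
    )
    Xo = X[:, order] * np.sqrt(w)[:, None]
    norms = np.linalg.norm(Xo, axis=0)
    zero = norms == 0
    norms[zero] = 1.0
    R = np.linalg.qr(Xo / norms, mode="r")
    diag = np.abs(np.diag(R))
    keep_mask = (diag > _RANK_TOL) & ~zero
    # Cascade: re-check after removing exact dependencies.
    while not keep_mask.all():
        kept = np.flatnonzero(keep_mask)
        R = np.linalg.qr(Xo[:, kept] / norms[kept], mode="r")
        diag = np.abs(np.diag(R))
        bad = kept[diag <= _RANK_TOL]
        if len(bad) == 0:
            break
        keep_mask[bad] = False
    kept_orig = [order[j] for j in np.flatnonzero(keep_mask)]
    dropped_orig = [order[j] for j in np.flatnonzero(~keep_mask)]
    for j in dropped_orig:
        if columns[j] in protected:
            raise EstimationError(
                f"protected column {columns[j]!r} is not identified by the design"
            )
    kept_orig.sort()
    dropped_names = [columns[j] for j in sorted(dropped_orig)]
    return X[:, kept_orig], [columns[j] for j in kept_orig], dropped_names


def fit_wls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    clusters: np.ndarray,
    columns: list[str] | None = None,
    small_sample: str = "CR1",
    ci_level: float = 0.95,
) -> FitResult:
    """Weighted least squares with the cluster-robust sandwich covariance.

    V = c * (X'WX)^-1 [ sum_g s_g s_g' ] (X'WX)^-1 with per-cluster score
    sums s_g = sum_{i in g} w_i e_i x_i, the CR1 factor
    c = G/(G-1) * (N-1)/(N-k), and confidence intervals from t(G-1).
    Estimates and the covariance are invariant to rescaling the weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n, k = X.shape
    if columns is None:
        columns = [f"x{j}" for j in range(k)]
    if n <= k:
        raise EstimationError(f"need more observations ({n}) than columns ({k})")
    labels, cluster_idx = np.unique(clusters, return_inverse=True)
    G = len(labels)
    if G < 2:
        raise EstimationError("clustered inference needs at least 2 clusters")
    if (w <= 0).any():
        raise ValidationError("weights must be positive")

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    Q, R = np.linalg.qr(Xw)
    diag = np.abs(np.diag(R))
    if diag.min() <= _RANK_TOL * max(diag.max(), 1.0):
        offenders = [columns[j] for j in np.flatnonzero(diag <= _RANK_TOL * diag.max())]
        raise EstimationError(f"singular normal equations; offending columns: {offenders}")
    beta = np.linalg.solve(R, Q.T @ yw)
    resid = y - X @ beta

    # Cluster score sums and the sandwich.
    M = X * (w * resid)[:, None]
    S = np.zeros((G, k))
    np.add.at(S, cluster_idx, M)
    meat = S.T @ S
    Rinv = np.linalg.solve(R, np.eye(k))
    bread = Rinv @ Rinv.T  # (X'WX)^-1
    if small_sample == "CR1":
        c = (G / (G - 1)) * ((n - 1) / (n - k))
    elif small_sample == "none":
        c = 1.0
    else:
        raise ValidationError("small_sample must be 'CR1' or 'none'")
    vcov = c * bread @ meat @ bread
    vcov = 0.5 * (vcov + vcov.T)

    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    crit = stats.t.ppf(0.5 + ci_level / 2.0, df=G - 1)
    ci_lo = beta - crit * se
    ci_hi = beta + crit * se

    ybar = np.sum(w * y) / np.sum(w)
    tss = np.sum(w * (y - ybar) ** 2)
    rss = np.sum(w * resid**2)
    r2 = 0.0 if tss == 0 else float(1.0 - rss / tss)

    idx = pd.Index(columns, name="term")
    return FitResult(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        ci_lo=pd.Series(ci_lo, index=idx),
        ci_hi=pd.Series(ci_hi, index=idx),
        vcov=pd.DataFrame(vcov, index=idx, columns=idx),
        r2=r2,
        n_obs=n,
        n_clusters=G,
        df=G - 1,
    )


def estimate_elasticity(
    children: pd.DataFrame,
    meta: pd.DataFrame,
    macro: pd.DataFrame,
    spec: ModelSpec,
    mean_prev: pd.Series | None = None,
) -> FitResult:
    """End-to-end: weights -> shock -> design -> weighted fit.

    The coefficient on ``shock`` is the elasticity — percent change in the
    outcome's prevalence per 10% change in per-capita income growth.
    """
    design = build_design(children, meta, macro, spec, mean_prev=mean_prev)
    fit = fit_wls(
        design.X,
        design.y,
        design.w,
        design.clusters,
        columns=design.columns,
        small_sample=spec.small_sample,
        ci_level=spec.ci_level,
    )
    fit.dropped_columns = design.dropped_columns
    fit.n_dropped_rows = design.n_dropped_rows
    fit.reference_levels = design.reference_levels
    fit.spec = spec
    return fit


def estimate_mechanism(
    children: pd.DataFrame,
    meta: pd.DataFrame,
    macro: pd.DataFrame,
    spec: ModelSpec,
    mean_prev: pd.Series | None = None,
) -> FitResult:
    """Mechanism variant: contemporaneous growth interacted with the
    mechanism outcome's own country mean."""
    if spec.outcome not in MECHANISM_OUTCOMES:
        raise ValidationError(
            f"mechanism outcome must be one of {MECHANISM_OUTCOMES}"
        )
    if spec.lag != 0:
        spec = replace(spec, lag=0)
    return estimate_elasticity(children, meta, macro, spec, mean_prev=mean_prev)


def estimate_subgroup(
    children: pd.DataFrame,
    meta: pd.DataFrame,
    macro: pd.DataFrame,
    spec: ModelSpec,
    mean_prev: pd.Series | None = None,
) -> FitResult:
    """Subgroup variant: adds shock x urban / shock x girl interactions."""
    if not spec.subgroup_interactions:
        raise ValidationError("spec.subgroup_interactions is empty")
    return estimate_elasticity(children, meta, macro, spec, mean_prev=mean_prev)
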