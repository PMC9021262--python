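import numpy as np
import pandas as pd
import pytest

from wastingshocks import (
    EstimationError,
    ModelSpec,
    ValidationError,
    build_design,
    estimate_elasticity,
    estimate_mechanism,
    estimate_subgroup,
    fit_wls,
)
from wastingshocks.macro import annual_growth
from wastingshocks.regression import _dummies, _prune_collinear
from wastingshocks.weighting import attach_weights

from conftest import brute_force_cluster_vcov, random_cluster_instance

BARE = dict(
    dhs_controls=False, region_age=False, region_month=False, region_bracket=False
)


@pytest.fixture
def tiny_macro():
    years = list(range(2000, 2012))
    rows = []
    rng = np.random.default_rng(2)
    for country in ("AA", "BB"):
        level = 100.0
        for year in years:
            rows.append({"country": country, "year": year, "gni_pc": level, "gdp_pc": level})
            level *= 1.0 + rng.normal(0.02, 0.05)
    return pd.DataFrame(rows)


class TestFitWls:
    def test_tiny_instance_matches_brute_force(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = rng.normal(size=12)
        w = rng.uniform(0.5, 2.0, 12)
        clusters = np.repeat([0, 1, 2], 4)
        fit = fit_wls(X, y, w, clusters)
        beta, vcov = brute_force_cluster_vcov(X, y, w, clusters)
        assert np.allclose(fit.params, beta, atol=1e-10)
        assert np.allclose(fit.vcov, vcov, atol=1e-10)

    def test_randomized_instances_match_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(15):
            X, y, w, clusters = random_cluster_instance(rng)
            fit = fit_wls(X, y, w, clusters)
            beta, vcov = brute_force_cluster_vcov(X, y, w, clusters)
            assert np.allclose(fit.params, beta, atol=1e-10)
            assert np.allclose(fit.vcov, vcov, atol=1e-10)

    def test_no_correction_variant(self):
        rng = np.random.default_rng(5)
        X, y, w, clusters = random_cluster_instance(rng)
        fit = fit_wls(X, y, w, clusters, small_sample="none")
        _, vcov = brute_force_cluster_vcov(X, y, w, clusters, small_sample=False)
        assert np.allclose(fit.vcov, vcov, atol=1e-10)

    def test_matches_statsmodels_point_estimates(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X, y, w, clusters = random_cluster_instance(rng)
        fit = fit_wls(X, y, w, clusters)
        ref = sm.WLS(y, X, weights=w).fit()
        assert np.allclose(fit.params, ref.params, atol=1e-9)

    def test_zero_outcome_all_zero_coefficients(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        fit = fit_wls(X, np.zeros(30), np.ones(30), np.repeat([0, 1, 2], 10))
        assert np.allclose(fit.params, 0.0)
        assert fit.r2 == 0.0

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(9)
        X, y, w, clusters = random_cluster_instance(rng)
        a = fit_wls(X, y, w, clusters)
        b = fit_wls(X, y, 2.0 * w, clusters)
        assert np.allclose(a.params, b.params, atol=1e-12)
        assert np.allclose(a.vcov, b.vcov, atol=1e-12)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(13)
        X, y, w, clusters = random_cluster_instance(rng)
        fit = fit_wls(X, y, w, clusters)
        assert (fit.ci_lo <= fit.params).all()
        assert (fit.params <= fit.ci_hi).all()
        assert np.allclose(fit.vcov, fit.vcov.T)

    def test_r2_nondecreasing_with_added_columns(self):
        rng = np.random.default_rng(11)
        n = 120
        X2 = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = rng.normal(size=n)
        w = np.ones(n)
        clusters = rng.integers(0, 6, n)
        r2_small = fit_wls(X2[:, :2], y, w, clusters).r2
        r2_big = fit_wls(X2, y, w, clusters).r2
        assert r2_big >= r2_small - 1e-12

    def test_singular_design_names_offenders(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(EstimationError, match="x1"):
            fit_wls(X, np.zeros(20), np.ones(20), np.repeat([0, 1], 10))

    def test_too_few_clusters_rejected(self):
        X = np.ones((10, 1))
        with pytest.raises(EstimationError, match="clusters"):
            fit_wls(X, np.zeros(10), np.ones(10), np.zeros(10))

    def test_more_columns_than_rows_rejected(self):
        X = np.ones((3, 4))
        with pytest.raises(EstimationError):
            fit_wls(X, np.zeros(3), np.ones(3), np.array([0, 1, 2]))


class TestDesign:
    def test_region_age_cell_count(self):
        # 2 regions x 60 ages -> 120 cells, one reference -> 119 columns.
        labels = pd.Series(
            [f"{r}|a{a:02d}" for r in ("R1", "R2") for a in range(60)]
        )
        refs = {}
        dummies = _dummies(labels, "region_age", refs)
        assert dummies.shape[1] == 119
        assert refs["region_age"] == "R1|a00"

    def test_single_country_no_country_dummies(self, tiny_children, tiny_meta, tiny_macro):
        ch = tiny_children[tiny_children["country"] == "AA"].reset_index(drop=True)
        spec = ModelSpec(outcome="mod_sev", mean_prev_source="meta", **BARE)
        design = build_design(ch, tiny_meta, tiny_macro, spec)
        assert not any(c.startswith("country=") for c in design.columns)

    def test_collinear_column_pruned_with_name(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        X = np.column_stack([X, X[:, 1]])  # exact duplicate
        cols = ["intercept", "shock", "dup"]
        Xp, kept, dropped = _prune_collinear(X, cols, np.ones(50), ("intercept", "shock"))
        assert kept == ["intercept", "shock"]
        assert dropped == ["dup"]

    def test_protected_column_unidentified_raises(self):
        X = np.column_stack([np.ones(50), np.zeros(50)])
        with pytest.raises(EstimationError, match="shock"):
            _prune_collinear(X, ["intercept", "shock"], np.ones(50), ("intercept", "shock"))

    def test_redundant_dummies_pruned_in_full_design(self, small_ds):
        spec = ModelSpec(outcome="mod_sev", mean_prev_source="meta")
        design = build_design(small_ds.children, small_ds.meta, small_ds.macro, spec)
        assert len(design.dropped_columns) > 0
        assert "shock" in design.columns
        # kept columns are linearly independent
        sw = np.sqrt(design.w)
        r = np.linalg.matrix_rank(design.X * sw[:, None])
        assert r == design.X.shape[1]

    def test_growth_trim_excludes_extreme_country_years(self, small_ds):
        # macro supplied as growth columns so exactly one cell is spiked
        gni = annual_growth(small_ds.macro, "gni").rename(columns={"growth": "gni_growth"})
        gdp = annual_growth(small_ds.macro, "gdp").rename(columns={"growth": "gdp_growth"})
        macro = gni.merge(gdp, on=["country", "year"])
        ch = small_ds.children
        country = ch["country"].iloc[0]
        year = int(ch.loc[ch["country"] == country, "interview_year"].iloc[0])
        spike = (macro["country"] == country) & (macro["year"] == year - 1)
        macro.loc[spike, "gni_growth"] = 400.0
        spec = ModelSpec(outcome="mod_sev", mean_prev_source="meta", **BARE)
        full = build_design(ch, small_ds.meta, macro, spec)
        trimmed = build_design(
            ch, small_ds.meta, macro,
            ModelSpec(outcome="mod_sev", mean_prev_source="meta",
                      growth_trim=(2.0, 98.0), **BARE),
        )
        n_spiked_cell = (
            (ch["country"] == country) & (ch["interview_year"] == year)
        ).sum()
        assert n_spiked_cell > 0
        assert len(trimmed.y) <= len(full.y) - n_spiked_cell

    def test_missing_outcome_column_rejected(self, tiny_children, tiny_meta, tiny_macro):
        ch = tiny_children.drop(columns=["wasting_severe"])
        spec = ModelSpec(outcome="severe", mean_prev_source="meta", **BARE)
        with pytest.raises(ValidationError):
            build_design(ch, tiny_meta, tiny_macro, spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(outcome="nonsense").validate()
        with pytest.raises(ValidationError):
            ModelSpec(measure="usd").validate()


class TestEstimateElasticity:
    def test_country_constant_growth_shift_absorbed_by_fe(self, small_ds):
        spec = ModelSpec(outcome="mod_sev", mean_prev_source="meta", **BARE)
        base = estimate_elasticity(small_ds.children, small_ds.meta, small_ds.macro, spec)
        growth = annual_growth(small_ds.macro, "gni").rename(
            columns={"growth": "gni_growth"}
        )
        growth.loc[growth["country"] == "C000", "gni_growth"] += 5.0
        gdp = annual_growth(small_ds.macro, "gdp").rename(columns={"growth": "gdp_growth"})
        shifted_macro = growth.merge(gdp, on=["country", "year"])
        shifted = estimate_elasticity(
            small_ds.children, small_ds.meta, shifted_macro, spec
        )
        assert shifted.beta_g == pytest.approx(base.beta_g, abs=1e-8)

    def test_composite_weight_rescaling_leaves_estimates_unchanged(self, small_ds):
        spec = ModelSpec(outcome="mod_sev", mean_prev_source="meta", **BARE)
        ch = attach_weights(small_ds.children, small_ds.meta)
        base = estimate_elasticity(ch, small_ds.meta, small_ds.macro, spec)
        scaled = ch.assign(composite_weight=ch["composite_weight"] * 123.4)
        again = estimate_elasticity(scaled, small_ds.meta, small_ds.macro, spec)
        assert np.allclose(base.params, again.params, atol=1e-10)

    def test_mean_prev_override_changes_regressor_scale(self, small_ds):
        spec = ModelSpec(outcome="mod_sev", **BARE)
        prev = small_ds.meta.set_index("country")["mean_prev_mod_sev"]
        a = estimate_elasticity(
            small_ds.children, small_ds.meta, small_ds.macro, spec, mean_prev=prev
        )
        b = estimate_elasticity(
            small_ds.children, small_ds.meta, small_ds.macro, spec, mean_prev=prev * 2
        )
        assert a.beta_g == pytest.approx(2 * b.beta_g, rel=1e-6)

    def test_summary_layout(self, small_ds):
        spec = ModelSpec(outcome="mod_sev", mean_prev_source="meta", **BARE)
        fit = estimate_elasticity(small_ds.children, small_ds.meta, small_ds.macro, spec)
        summ = fit.summary()
        assert list(summ.columns) == [
            "term", "estimate", "se_clustered", "ci_lo", "ci_hi", "block",
        ]
        assert (summ.loc[summ["term"] == "shock", "block"] == "shock").all()


class TestMechanismAndSubgroup:
    def test_mechanism_requires_mechanism_outcome(self, small_ds):
        with pytest.raises(ValidationError):
            estimate_mechanism(
                small_ds.children, small_ds.meta, small_ds.macro,
                ModelSpec(outcome="mod_sev", **BARE),
            )

    def test_mechanism_forces_contemporaneous_lag(self, mech_ds):
        spec = ModelSpec(outcome="diarrhea", lag=1, mean_prev_source="meta", **BARE)
        fit = estimate_mechanism(mech_ds.children, mech_ds.meta, mech_ds.macro, spec)
        assert fit.spec.lag == 0

    def test_mdd_sample_restricted_to_6_35_months(self, mech_ds):
        spec = ModelSpec(outcome="mdd", lag=0, mean_prev_source="meta", **BARE)
        fit = estimate_mechanism(mech_ds.children, mech_ds.meta, mech_ds.macro, spec)
        eligible = mech_ds.children["age_months"].between(6, 35).sum()
        assert fit.n_obs == eligible

    def test_subgroup_interaction_columns_present(self, small_ds):
        spec = ModelSpec(
            outcome="mod_sev", mean_prev_source="meta",
            subgroup_interactions=("urban", "girl"), **BARE,
        )
        fit = estimate_subgroup(small_ds.children, small_ds.meta, small_ds.macro, spec)
        assert "shock_x_urban" in fit.params.index
        assert "shock_x_girl" in fit.params.index

    def test_constant_subgroup_interaction_dropped(self, small_ds):
        ch = small_ds.children.assign(rural=1)
        spec = ModelSpec(
            outcome="mod_sev", mean_prev_source="meta",
            subgroup_interactions=("urban",), **BARE,
        )
        fit = estimate_subgroup(ch, small_ds.meta, small_ds.macro, spec)
        assert "shock_x_urban" not in fit.params.index

    def test_empty_subgroup_spec_rejected(self, small_ds):
        with pytest.raises(ValidationError):
            estimate_subgroup(
                small_ds.children, small_ds.meta, small_ds.macro,
                ModelSpec(outcome="mod_sev", **BARE),
            )

    def test_planted_subgroup_differential_recovered(self, small_cfg):
        # Re-draw the outcome with an urban-specific extra elasticity, then
        # check the interaction coefficient lands near the planted value.
        import wastingshocks as ws
        from wastingshocks.simulate import with_seed

        cfg = ws.SimConfig(n_countries=30, children_per_round=700,
                           rounds_min=3, rounds_max=3, seed=101)
        ds = ws.generate_dataset(cfg)
        ch = ds.children
        g = annual_growth(ds.macro, "gni").set_index(["country", "year"])["growth"]
        g_pct = pd.MultiIndex.from_arrays(
            [ch["country"], ch["interview_year"] - 1]
        ).map(g).to_numpy()
        pbar = ch["country"].map(
            {c: v["mod_sev"] for c, v in ds.truth["baseline_prev"].items()}
        ).to_numpy()
        urban = 1.0 - ch["rural"].to_numpy()
        beta0, beta_u = -0.15, -0.05
        p = np.clip(pbar * (1.0 + (beta0 + beta_u * urban) * g_pct / 10.0), 0.001, 0.999)
        rng = np.random.default_rng(202)
        ch = ch.assign(wasting_mod_sev=(rng.random(len(ch)) < p).astype(int))
        spec = ModelSpec(
            outcome="mod_sev", mean_prev_source="meta",
            subgroup_interactions=("urban",), **BARE,
        )
        fit = estimate_subgroup(ch, ds.meta, ds.macro, spec)
        est = fit.params["shock_x_urban"]
        se = fit.se["shock_x_urban"]
        assert abs(est - beta_u) < max(3 * se, 0.05)

    def test_null_girl_interaction_ci_covers_zero(self, small_cfg):
        import wastingshocks as ws

        cfg = ws.SimConfig(n_countries=25, children_per_round=400,
                           rounds_min=3, rounds_max=3, seed=55)
        ds = ws.generate_dataset(cfg)
        spec = ModelSpec(
            outcome="mod_sev", mean_prev_source="meta",
            subgroup_interactions=("girl",), **BARE,
        )
        fit = estimate_subgroup(ds.children, ds.meta, ds.macro, spec)
        lo, hi = fit.ci("shock_x_girl")
        assert lo <= 0 <= hi
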