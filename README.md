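# wastingshocks

A tested pipeline for estimating how macroeconomic growth shocks affect
child wasting prevalence, and for projecting wasting burdens from new
shocks:

- **simulate** — a seeded synthetic multi-country survey + macro data
  generator with a *planted* elasticity, so every downstream stage is
  testable without access-restricted survey microdata;
- **weighting** — a three-step composite weight (country under-5 population
  share → equal round totals within country → survey design weights) that
  makes pooled regressions representative of the under-5 population;
- **outcomes** — wasting classification from weight-for-height z-scores
  (any < −1, moderate/severe < −2, severe < −3, strict cutoffs), weighted
  prevalences, prevalence bands, and kernel-smoothed age profiles;
- **macro** — annual percent growth from per-capita income levels, long-run
  mean prevalence, and the shock × prevalence interaction regressor (growth
  in units of a 10% change, prevalence as a proportion, one-year lag);
- **regression** — the weighted linear probability model with country fixed
  effects, region-specific temporal effects (age-in-months, interview
  month, 5-year brackets), household controls, and country-clustered
  sandwich inference (CR1, t(G−1)). The coefficient on the interaction is
  an elasticity: percent change in prevalence per 10% change in income.
  Mechanism (contemporaneous growth, outcome-specific country means) and
  subgroup (urban/girl interaction) variants included;
- **projection** — the burden calculator: shock = crisis-year growth minus
  decade-mean growth; projected prevalence = baseline × (1 + elasticity ×
  shock/10); wasted-child counts with regional and total aggregation.

## CLI

```bash
# generate a synthetic dataset (children.csv, macro.csv, countries.csv, truth.json)
wastingshocks simulate --out-dir simdata --n-countries 40 --seed 1

# attach composite three-step weights
wastingshocks weights --children simdata/children.csv \
    --countries simdata/countries.csv --out children_weighted.csv

# six-regression sweep: three wasting outcomes x GNI/GDP
wastingshocks fit --children simdata/children.csv --macro simdata/macro.csv \
    --countries simdata/countries.csv --out-dir fits

# mechanism regressions (contemporaneous growth)
wastingshocks simulate --out-dir simdata --mechanisms --seed 1
wastingshocks mechanisms --children simdata/children.csv \
    --macro simdata/macro.csv --countries simdata/countries.csv --out-dir mech

# burden projection from a user-supplied country table
wastingshocks project --input projection_input.csv --out projection_output.csv \
    --elasticity -0.178

# collect fitted elasticities into one summary table
wastingshocks report --fit-dir fits --out report.csv
```

Every subcommand also accepts `--config cfg.yaml` (keys matching the option
names; explicit options win). A full template ships at
`src/wastingshocks/data/default_config.yaml`. File schemas are documented
in `SCHEMAS.md`. Exit codes: 0 success, 2 validation error, 3 estimation
failure.

## Notes on conventions

- Composite weights are rescaled to sum to the number of child records;
  all weighted-least-squares point estimates are invariant to this choice
  (tested).
- Long-run mean prevalence enters the interaction as a proportion, so the
  fitted coefficient reads directly as a relative (percent) change in
  prevalence per 10% growth change.
- 5-year brackets are anchored at 1990; reference categories are the
  lexicographically first level per dummy block ("no assets" for the asset
  class) and are recorded in the fit metadata.
- Exactly collinear columns are pruned with their names logged; the shock
  regressor is protected and its non-identification is a hard error.
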