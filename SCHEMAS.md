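# File schemas

All files are UTF-8 CSV, snake_case headers, `.` decimal separator, empty
string for missing values.

## children.csv

One row per measured child.

| column | type | notes |
|---|---|---|
| country | string | country code |
| region | string | one of the region roster labels |
| round_id | string | survey round identifier, unique within country |
| interview_year | int | calendar year of measurement |
| interview_month | int | 1–12 |
| age_months | int | 0–59 |
| whz | float | weight-for-height z-score (optional if indicators given) |
| wasting_any / wasting_mod_sev / wasting_severe | 0/1 | nested indicators (severe ⊆ mod_sev ⊆ any) |
| asset_class | string | `none`, `some`, or `all` (five-asset ownership class) |
| maternal_education_years | int | |
| piped_water, flush_toilet, facility_birth, anc4, fully_vaccinated, teen_birth, parity_4plus, female, rural | 0/1 | household / maternal / child controls |
| design_weight | float > 0 | survey design weight |
| diarrhea, fever_only, low_mbmi, mdd | 0/1 | mechanism outcomes (optional); `mdd` only for ages 6–35 months, missing otherwise |
| composite_weight | float > 0 | added by the `weights` stage |

## macro.csv

One row per country-year. Either level columns (preferred) or pre-computed
percent growth columns are accepted.

| column | type | notes |
|---|---|---|
| country | string | |
| year | int | |
| gni_pc, gdp_pc | float > 0 | per-capita income levels |
| gni_growth, gdp_growth | float | percent per annum (alternative to levels) |

## countries.csv

One row per country.

| column | type | notes |
|---|---|---|
| country | string | |
| region | string | roster label |
| pop_u5 | float > 0 | under-5 population |
| mean_prev_any / mean_prev_mod_sev / mean_prev_severe | float | long-run prevalence in percent (used when `mean_prev_source: meta`) |
| mean_prev_diarrhea / … / mean_prev_mdd | float | mechanism means (optional) |

## truth.json

Sidecar written by `simulate`: planted parameters (`beta_true`,
`shock_measure`, per-country baseline prevalences, covariate effects,
mechanism elasticities, clamp fraction).

## projection_input.csv

One row per country.

| column | type | notes |
|---|---|---|
| country | string | must be unique |
| grouping | string | aggregation label (empty → `all`) |
| g2020 | float | percent GDP growth in the shock year |
| g_decade_mean | float | mean percent growth over the preceding decade |
| prev2019 | float | baseline moderate/severe wasting prevalence, percent |
| pop_u5 | float > 0 | under-5 population |

## projection_output.csv / *_aggregates.csv

Per-country rows add `shock`, `prev2021`, `wasted2019`, `wasted2021`,
`change` (and `prev2021_lo/hi`, `change_lo/hi` for CI-band runs). The
aggregates file sums counts by `grouping` plus a `Total` row;
shock/prevalence columns there are population-weighted means.

## Fit outputs

`fit_<outcome>_<measure>.csv`: tidy per-term table — `term`, `estimate`,
`se_clustered`, `ci_lo`, `ci_hi`, `block`. A companion
`fit_<outcome>_<measure>_meta.txt` records N, cluster count, R², the
elasticity with its CI, dropped rows/columns and reference levels.
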