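# Full default configuration template for the `wastingshocks` CLI.
# Each subcommand reads the keys it understands; explicit command-line
# options override values given here.

# ---- simulate ---------------------------------------------------------
out_dir: simdata
seed: 0
n_countries: 40
year_start: 1990
year_end: 2018
rounds_min: 2
rounds_max: 4
children_per_round: 2000
beta_true: -0.15
baseline_prev_range: [0.03, 0.25]
growth_trend_mean: 0.02
growth_trend_sd: 0.01
growth_shock_sd: 0.05
gni_gdp_corr: 0.90
shock_measure: gni
asset_shares: [0.34, 0.59, 0.07]
round_size_multiplier_range: [0.25, 4.0]
clamp_bounds: [0.001, 0.999]
max_clamp_frac: 0.01
mechanisms: false

# ---- weights / fit / mechanisms --------------------------------------
children: simdata/children.csv
macro: simdata/macro.csv
countries: simdata/countries.csv
# outcomes: [any, mod_sev, severe]
# measures: [gni, gdp]
mean_prev_source: data
# growth_trim: [1, 99]
# subgroup_interactions: [urban, girl]
# extra_controls: []

# ---- project ----------------------------------------------------------
# input: projection_input.csv
# out: projection_output.csv
# elasticity: -0.178
# ci_lo: -0.312
# ci_hi: -0.044
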