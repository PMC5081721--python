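# Example run configuration: EU-level trans-fat policy cost-effectiveness model.
#
# Omitted fields take the model defaults: 85-year horizon, 3.5% annual
# discount rate on costs and effects, all four policy options, base-case
# initial iTFA intake of 0.3 E%, 2011-euro cost set, RR 1.23 per 2 E%
# (95% CI 1.11-1.37).

horizon_years: 85
discount_rate: 0.035
scenario: base
options: [reference, voluntary, labeling, legal_limit]
decay_shape: linear

daly:
  # Disability weights are external inputs sourced from the published
  # GBD 2010 weight tables: the acute value is a time-weighted average of the
  # acute-myocardial-infarction and post-event angina sequela weights over
  # the one-year acute state; the history value is moderate angina pectoris.
  disability_weight_acute: 0.080
  disability_weight_history: 0.080
  acute_duration: 1.0
  discount_effects: true

thresholds:
  gdp_per_capita: 23300.0

psa:
  n_draws: 1000
  seed: 42
  se_fraction: 0.2
  table_cv: 0.2
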