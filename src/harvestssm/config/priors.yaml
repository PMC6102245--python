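# Packaged default prior set for the statewide age-at-harvest model.
#
# Recruitment parameters are on the natural scale (gamma / beta families).
# Survival-type parameters are hierarchical on the complementary log-log
# mortality link scale: the long-term mean has a normal prior centred at
# link(mean) with the stated precision (1/variance); year-varying
# parameters additionally carry a gamma hyperprior on the annual
# link-scale precision.
schema_version: 1
recruitment:
  litter_size:
    "2.5": {family: gamma, shape: 20.0, rate: 10.0}
    "3.5": {family: gamma, shape: 20.0, rate: 10.0}
    "4.5": {family: gamma, shape: 20.0, rate: 10.0}
    "5.5+": {family: gamma, shape: 16.4, rate: 6.0}
  pregnancy_rate:
    "2.5": {family: beta, alpha: 2.61, beta: 1000.0}
    "3.5": {family: beta, alpha: 34.0, beta: 100.0}
    "4.5": {family: beta, alpha: 54.0, beta: 48.0}
    "5.5+": {family: beta, alpha: 47.0, beta: 50.0}
  sex_proportion_female: {family: beta, alpha: 426.0, beta: 500.0}
survival:
  link: cloglog-mortality
  harvest_season:
    female:
      mean: 0.85
      long_term_precision: 3.0
      annual_precision_prior: {shape: 20.0, rate: 0.5}
    male:
      mean: 0.77
      long_term_precision: 3.0
      annual_precision_prior: {shape: 20.0, rate: 0.5}
  non_harvest:
    mean: 0.95
    long_term_precision: 4.0
    annual_precision_prior: {shape: 20.0, rate: 0.5}
  cub_a: {mean: 0.84, long_term_precision: 4.0}
  cub_b: {mean: 0.71, long_term_precision: 4.0}
  reporting: {mean: 0.98, long_term_precision: 2.0}
age_offsets:
  # link-scale age-class offsets on harvest-season survival: one free
  # offset for each of the three youngest classes, reference class 4+
  # fixed at zero.
  n_offset_classes: 3
  sd: 1.0
initial_population:
  n_total: 21450
  # lognormal spread (sd of log total) of the initial-population prior
  dispersion: 0.2
  # mean share of each age class in the registered harvest over the three
  # decades preceding the study window (yearling-heavy, with the absorbing
  # terminal class accumulating survivors)
  age_class_proportions:
    [0.21, 0.17, 0.13, 0.10, 0.08, 0.06, 0.05, 0.04, 0.03, 0.13]
  male_fraction: 0.55
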