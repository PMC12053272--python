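# Trait-to-metric calibration for the virtual-respondent model.
#
# Reaction times follow  rt = t0 + exp(N(rt_logmedian + condition_cost
# - rt_ability_slope * eta, sigma))  in milliseconds; accuracy follows
# P(correct) = (1 - lapse) * logistic(accuracy_slope * eta + accuracy_logit
# + condition_logit).  Constants are chosen so that default cohorts land
# inside published ranges for comparable tasks (e.g. basic response time
# means within 231-518 ms).
schema_version: 1

rt_ability_slope: 0.10      # log-ms decrease per SD of ability
accuracy_slope: 1.0         # logit increase per SD of ability
span_slope: 1.2             # logistic slope on (capacity - sequence length)
span_capacity_base:
  span_fwd: 5.8
  span_bwd: 5.3
span_capacity_per_sd: 1.0
anticipatory_rt_range: [80.0, 199.0]

nuisance_ranges:            # uniform ranges for per-respondent parameters
  t0_ms: [120.0, 200.0]
  sigma: [0.15, 0.30]
  lapse: [0.01, 0.05]
  anticipatory: [0.005, 0.02]

tasks:
  basic_rt:      {rt_logmedian: 5.20, accuracy_logit: 4.0}
  span_fwd:      {rt_logmedian: 6.90, accuracy_logit: 0.0}
  span_bwd:      {rt_logmedian: 7.00, accuracy_logit: 0.0}
  flanker:
    rt_logmedian: 5.55
    accuracy_logit: 3.0
    condition_costs: {congruent: 0.0, incongruent: 0.10}
    condition_logits: {congruent: 0.3, incongruent: -0.4}
  cpt_impulsive: {rt_logmedian: 5.30, accuracy_logit: 3.2, nogo_logit: 2.5}
  cpt_sustained: {rt_logmedian: 5.60, accuracy_logit: 3.2, nogo_logit: 2.5}
  stroop:
    rt_logmedian: 6.10
    accuracy_logit: 2.4
    condition_costs: {congruent: 0.0, incongruent: 0.12}
    condition_logits: {congruent: 0.3, incongruent: -0.4}
  boxed:
    rt_logmedian: 6.20
    accuracy_logit: 2.8
    condition_costs:
      feature_4: 0.0
      feature_12: 0.15
      conjunction_4: 0.20
      conjunction_12: 0.50
  compass:
    rt_logmedian: 5.70
    accuracy_logit: 2.4
    condition_costs: {neutral: 0.0, congruent: -0.05, incongruent: 0.10}
    condition_logits: {neutral: 0.0, congruent: 0.2, incongruent: -0.3}
  taskswitch:
    rt_logmedian: 6.30
    accuracy_logit: 2.2
    condition_costs: {stay: 0.0, switch: 0.20}
    condition_logits: {stay: 0.2, switch: -0.3}
  tap_trace:
    rt_logmedian: 6.00
    accuracy_logit: 3.2
    nogo_logit: 2.5
    condition_costs: {tap: 0.0, dual: 0.25}

groups:                     # age-group differences; edges stay identical
  younger: {mean_shift: 0.0, scale: 1.0, age_range: [18, 39]}
  older:   {mean_shift: -0.4, scale: 0.8, age_range: [40, 75]}

test_retest_r: 0.70         # session-to-session ability stability
concurrent_r: 0.45          # comparator-battery attenuation (lambda_cv)
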