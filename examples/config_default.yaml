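# Default model inputs (the published base case).
# Every key can be overridden; omitted keys keep these defaults.
# Point estimates with printed 95% CIs are written as {value, ci_low, ci_high};
# overriding one with a bare number replaces the value and drops the CI.
# Age-banded tables map the band's lower bound (closed-open bands; ages above
# the top band use the top band) to the annual value.
effect:
  hr_hip:
    value: 0.62
    ci_low: 0.52
    ci_high: 0.75
  hr_vertebral:
    value: 0.63
    ci_low: 0.52
    ci_high: 0.75
  hr_nonvertebral:
    value: 0.62
    ci_low: 0.53
    ci_high: 0.73
rates:
  hip:
    value: 0.017
    ci_low: 0.016
    ci_high: 0.019
  vertebral:
    value: 0.017
    ci_low: 0.015
    ci_high: 0.018
  other:
    value: 0.004
    ci_low: 0.003
    ci_high: 0.005
mortality:
  well_annual:
    70: 0.041
    80: 0.089
    90: 0.168
  rr_first_year:
    hip:
      70: 1.57
      80: 1.46
      90: 1.5
    vertebral:
      70: 1.26
      80: 1.18
      90: 1.15
    other:
      70: 0.97
      80: 1.01
      90: 1.72
  rr_subsequent:
    hip:
      70: 1.69
      80: 1.37
      90: 1.12
    vertebral:
      70: 1.27
      80: 1.0
      90: 1.15
  excess_duration_years:
    hip: 8.0
    vertebral: 8.0
    other: 1.0
costs:
  fracture_first_year:
    hip:
      70: 4315.0
      80: 4395.0
      90: 3930.0
    vertebral:
      70: 1604.0
      80: 1844.0
      90: 1354.0
    other:
      70: 1117.0
      80: 1571.0
      90: 1281.0
  fracture_subsequent_annual:
    hip: 1163.0
    vertebral: 734.0
  drug_annual: 400.0
  visit_routine: 10.54
  visit_nurse: 12.04
  dxa_scan: 20.01
utilities:
  well_by_age:
    75: 0.669
    80: 0.655
    85: 0.643
  multiplier_first_year:
    hip:
      value: 0.55
      ci_low: 0.53
      ci_high: 0.57
    vertebral:
      value: 0.68
      ci_low: 0.65
      ci_high: 0.7
    other:
      value: 0.83
      ci_low: 0.82
      ci_high: 0.84
  multiplier_subsequent:
    hip:
      value: 0.86
      ci_low: 0.84
      ci_high: 0.89
    vertebral:
      value: 0.85
      ci_low: 0.82
      ci_high: 0.87
settings:
  start_age: 77.0
  cycle_length: 0.5
  max_age: 110.0
  discount_rate_costs: 0.03
  discount_rate_qalys: 0.03
  intended_treatment_years: 5.0
  annual_discontinuation_rate: 0.317
  offset_years: 2.0
  wtp_threshold: 30038.0
  psa_iterations: 1000
  rng_seed: 20211012
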