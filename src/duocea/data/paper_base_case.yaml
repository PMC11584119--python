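meta:
  description: 'Base case: 100,000 patients with chronic liver disease suspected of
    having esophageal varices; DuO test at $3,250.'
population:
  cohort_size: 100000
  fraction_dsi_above:
    minimum: 0.3
    mode: 0.51
    maximum: 0.7
  varices_overall:
    no_varices: 0.66
    small_varices: 0.24
    large_varices: 0.1
  varices_above:
    no_varices: 0.48
    small_varices: 0.33
    large_varices: 0.19
  varices_below:
    no_varices: 0.8484848484848485
    small_varices: 0.14141414141414144
    large_varices: 0.010101010101010102
  small_vh_above:
    minimum: 0.04000000000000001
    mode: 0.05
    maximum: 0.06
  small_vh_below:
    minimum: 0.0008
    mode: 0.001
    maximum: 0.0012
  large_untreated_vh:
    minimum: 0.12
    mode: 0.15
    maximum: 0.18
  large_treated_event:
    minimum: 0.016
    mode: 0.02
    maximum: 0.024
  treated_fraction_above: 1.0
  treated_fraction_below: 0.0
performance:
  dsi_cutoff: 18.3
  sensitivity_small: 0.709
  sensitivity_large: 0.934
transitions:
  no_varices_to_dc_overall:
    minimum: 0.032
    mode: 0.04
    maximum: 0.048
  no_varices_to_dc_above:
    minimum: 0.066
    mode: 0.066
    maximum: 0.066
  no_varices_to_dc_below:
    minimum: 0.016
    mode: 0.02
    maximum: 0.024
  small_varices_to_dc_overall:
    minimum: 0.0664
    mode: 0.083
    maximum: 0.09960000000000001
  small_varices_to_dc_above:
    minimum: 0.119
    mode: 0.119
    maximum: 0.119
  small_varices_to_dc_below:
    minimum: 0.027200000000000002
    mode: 0.034
    maximum: 0.0408
  below_to_above_migration:
    minimum: 0.02
    mode: 0.025
    maximum: 0.03
  large_untreated_to_dc:
    minimum: 0.10800000000000001
    mode: 0.135
    maximum: 0.162
  large_treated_to_dc_overall:
    minimum: 0.10960000000000002
    mode: 0.137
    maximum: 0.16440000000000002
  large_treated_to_dc_above:
    minimum: 0.10800000000000001
    mode: 0.135
    maximum: 0.162
  vh_to_death:
    minimum: 0.10320000000000001
    mode: 0.129
    maximum: 0.1548
  post_treatment_vh_to_death:
    minimum: 0.10320000000000001
    mode: 0.129
    maximum: 0.1548
  rebleed_to_death:
    minimum: 0.10320000000000001
    mode: 0.129
    maximum: 0.1548
  dc_to_death:
    minimum: 0.10320000000000001
    mode: 0.129
    maximum: 0.1548
  egd_to_death_per_procedure:
    minimum: 8.000000000000001e-06
    mode: 1.0e-05
    maximum: 1.2e-05
  dc_reduction_on_adherence:
    minimum: 0.2
    mode: 0.35
    maximum: 0.5
  all_cause_mortality_annual: 0.0
costs:
  no_varices:
    minimum: 116.0
    mode: 145.0
    maximum: 174.0
  small_varices_no_vh:
    minimum: 124.0
    mode: 155.0
    maximum: 186.0
  small_varices_vh:
    minimum: 4008.0
    mode: 5010.0
    maximum: 6012.0
  large_treated:
    minimum: 585.0
    mode: 1110.0
    maximum: 1332.0
  large_treated_rebleed:
    minimum: 4008.0
    mode: 5010.0
    maximum: 6012.0
  large_untreated_no_vh:
    minimum: 124.0
    mode: 155.0
    maximum: 186.0
  large_untreated_vh:
    minimum: 4008.0
    mode: 5010.0
    maximum: 6012.0
  dc_first_year:
    minimum: 16430.0
    mode: 25595.0
    maximum: 30714.0
  dc_subsequent:
    minimum: 4690.0
    mode: 24755.0
    maximum: 29706.0
  egd:
    minimum: 1882.0
    mode: 2642.0
    maximum: 3641.0
  standard_labs_afp:
    minimum: 475.0
    mode: 475.0
    maximum: 570.0
  ultrasound_hcc:
    minimum: 745.0
    mode: 745.0
    maximum: 894.0
  duo_test_price: 3250.0
utilities:
  no_varices:
    minimum: 0.72
    mode: 0.92
    maximum: 1.0
  small_no_vh:
    minimum: 0.77
    mode: 0.79
    maximum: 0.81
  small_vh:
    minimum: 0.44
    mode: 0.69
    maximum: 0.69
  large_treated_no_event:
    minimum: 0.79
    mode: 0.83
    maximum: 0.87
  large_treated_event:
    minimum: 0.44
    mode: 0.69
    maximum: 0.69
  large_untreated_no_vh:
    minimum: 0.7
    mode: 0.76
    maximum: 0.79
  large_untreated_vh:
    minimum: 0.44
    mode: 0.69
    maximum: 0.69
  dc:
    minimum: 0.44
    mode: 0.69
    maximum: 0.69
economics:
  discount_rate: 0.03
  ce_threshold: 20000.0
  horizon: 10
options:
  vh_mixing: static
  discount_offset: 1
  initial_test_mode: add
  competing_exits: additive
  large_treated_rate: stratified
  treated_event_cost: rebleed
  repeat_duo_above: false
  accrual: midyear_care
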