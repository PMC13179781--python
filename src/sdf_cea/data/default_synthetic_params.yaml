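costs:
  c_access:
    base: 129.0
    high: 165.0
    low: 93.0
  c_exam:
    base: 36.0
    high: 45.0
    low: 27.0
  c_naf:
    base: 33.0
    high: 39.0
    low: 27.0
  c_sdf:
    base: 39.0
    high: 47.0
    low: 31.0
  c_xray:
    base: 45.0
    high: 53.0
    low: 37.0
  currency: 2025 US$
psa_specs:
  costs.c_access:
    ci95:
    - 95.53777807722025
    - 167.40891712273842
    family: gamma
    mean: 129.0
  costs.c_exam:
    ci95:
    - 27.567058354601578
    - 45.54111881859046
    family: gamma
    mean: 36.0
  costs.c_naf:
    ci95:
    - 27.27343087295585
    - 39.26416621887303
    family: gamma
    mean: 33.0
  costs.c_sdf:
    ci95:
    - 31.41209565175991
    - 47.39645984793358
    family: gamma
    mean: 39.0
  costs.c_xray:
    ci95:
    - 37.35635513190546
    - 53.344531373271806
    family: gamma
    mean: 45.0
  transition.naf.p_extract_caries:
    ci95:
    - 0.5967676097757122
    - 0.7766210179372232
    family: beta
    mean: 0.6902991496109137
  transition.naf.p_extract_nocaries:
    ci95:
    - 0.21466799296039102
    - 0.39290872697571405
    family: beta
    mean: 0.29999999999151783
  transition.naf.p_incidence_tx:
    ci95:
    - 0.002455990793531889
    - 0.0549968231994524
    family: beta
    mean: 0.02000000000001314
  transition.p_incidence_nat:
    ci95:
    - 0.002455990793531889
    - 0.0549968231994524
    family: beta
    mean: 0.02000000000001314
  transition.p_init_caries:
    ci95:
    - 0.5858583886579722
    - 0.7673217154692981
    family: beta
    mean: 0.68
  transition.sdf.p_arrest:
    ci95:
    - 0.06167155831584538
    - 0.1859721285097954
    family: beta
    mean: 0.1165866535666358
  transition.sdf.p_extract_caries:
    ci95:
    - 0.2600533974531309
    - 0.44563069764403135
    family: beta
    mean: 0.35
settings:
  charge_schedule: both_half_cycles
  cost_aggregation: cohort_sum
  cost_allocation: per_visit_shared
  cycles_per_year: 2
  discount_rate: 0.03
  effect_aggregation: per_tooth_mean
  horizon_years: 19
  n_teeth: 21
  start_age: 45.0
  wtp: 50000.0
transition:
  naf:
    p_arrest: 0.0
    p_extract_caries: 0.6902991496109137
    p_extract_nocaries: 0.29999999999151783
    p_incidence_tx: 0.02000000000001314
  p_incidence_nat: 0.02000000000001314
  p_init_caries: 0.68
  sdf:
    p_arrest: 0.1165866535666358
    p_extract_caries: 0.35
    p_extract_nocaries: 0.0
    p_incidence_tx: 0.0
utilities:
  ARREST: 1.0
  EXTRACTED: 0.0
  NO_CARIES: 1.0
  PERSISTENT: 1.0
  ROOT_CARIES: 1.0
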