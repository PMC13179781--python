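{
  "achieved": {
    "cost_NAF": 8651.532375715598,
    "effect_NAF": 1.397103172035422,
    "cost_SDF": 18282.635876624452,
    "effect_SDF": 7.180595896930368
  },
  "residuals": {
    "cost_NAF": -0.023859598813539617,
    "effect_NAF": 0.005110195708936683,
    "cost_SDF": 0.09739711144204394,
    "effect_SDF": -0.0710742694786071
  },
  "loss": 0.015133143654898212,
  "converged": false,
  "modes": {
    "cost_allocation": "per_visit_shared",
    "charge_schedule": "both_half_cycles",
    "effect_aggregation": "per_tooth_mean",
    "cost_aggregation": "cohort_sum"
  },
  "transition": {
    "p_init_caries": 0.68,
    "p_incidence_nat": 0.02000000000001314,
    "sdf": {
      "p_incidence_tx": 0.0,
      "p_extract_nocaries": 0.0,
      "p_arrest": 0.1165866535666358,
      "p_extract_caries": 0.35
    },
    "naf": {
      "p_incidence_tx": 0.02000000000001314,
      "p_extract_nocaries": 0.29999999999151783,
      "p_arrest": 0.0,
      "p_extract_caries": 0.6902991496109137
    }
  },
  "note": "Synthetic calibrated stand-in: transition probabilities fitted to the reference base-case outcomes, not measured clinical estimates."
}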