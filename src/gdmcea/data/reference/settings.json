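{
 "gdm_prevalence_population": 0.0065,
 "provenance": {
  "cohorts": "synthetic",
  "costs.intervention_cost_base": "fixture",
  "costs.other": "synthetic",
  "epi": "synthetic",
  "relative_risks": "fixture",
  "utilities": "fixture"
 },
 "reference_healthy_utility": 0.95,
 "t2dm_cost_scale": 1.0,
 "utility_adjustment_mode": "multiplicative"
}
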