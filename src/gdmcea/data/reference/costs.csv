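item,age_low,age_high,mean,lower95,upper95,distribution
intervention_cost_base,,,228.0,,,gamma
intervention_cost_diet,,,177.0,,,gamma
intervention_cost_pa,,,197.0,,,gamma
intervention_cost_diet_pa,,,228.0,,,gamma
antenatal_gdm_cost,,,1200.0,,,gamma
caesarean_cost,,,14000.0,,,gamma
induction_cost,,,4000.0,,,gamma
nicu_admission_cost,,,14000.0,,,gamma
microcost_first_year,,,3300.0,,,gamma
microcost_subsequent_year,,,1900.0,,,gamma
societal_direct_nonhealth,,,1650.0,,,gamma
societal_income_subsidy,,,2500.0,,,gamma
p_caesarean_gdm,,,0.37,,,
p_caesarean_no_gdm,,,0.33,,,
p_induction_gdm,,,0.44,,,
p_induction_no_gdm,,,0.38,,,
p_nicu_scn_gdm,,,0.306,,,
p_nicu_scn_no_gdm,,,0.17,,,
t2dm_annual_cost,15.0,39.0,950.0,,,
t2dm_annual_cost,40.0,49.0,1100.0,,,
t2dm_annual_cost,50.0,59.0,1250.0,,,
t2dm_annual_cost,60.0,69.0,1400.0,,,
t2dm_annual_cost,70.0,79.0,1550.0,,,
t2dm_annual_cost,80.0,85.0,1650.0,,,
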