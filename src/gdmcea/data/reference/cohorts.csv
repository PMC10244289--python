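band_label,age_low,age_high,representative_age,n_births,gdm_prevalence,preexisting_dm_prevalence
15-19,15,19,17,7665.0,0.06,0.002
20-24,20,24,22,36792.0,0.08,0.004
25-29,25,29,27,82782.0,0.1,0.007
30-34,30,34,32,106084.0,0.13,0.01
35-39,35,39,37,58254.0,0.17,0.015
40-44,40,44,42,13797.0,0.215,0.025
45-49,45,49,47,1226.0,0.25,0.035
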