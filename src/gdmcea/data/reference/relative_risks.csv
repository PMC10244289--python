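parameter,mean,lower95,upper95,distribution
rr_t2dm_after_gdm,9.51,7.14,12.67,lognormal
rr_gdm_base,0.67,0.58,0.77,lognormal
rr_gdm_diet,0.66,0.5,0.85,lognormal
rr_gdm_pa,0.62,0.5,0.77,lognormal
rr_gdm_diet_pa,0.75,0.58,0.97,lognormal
rr_t2dm_avoided_gdm,1.0,,,
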