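band_label,age_low,age_high,mean,lower95,upper95,distribution
18-24,18.0,24.0,0.95,0.92,0.98,beta
25-34,25.0,34.0,0.95,0.9,0.99,beta
35-44,35.0,44.0,0.91,0.86,0.96,beta
45-54,45.0,54.0,0.87,0.81,0.93,beta
55-64,55.0,64.0,0.88,0.82,0.94,beta
65-74,65.0,74.0,0.87,0.8,0.94,beta
75+,75.0,120.0,0.82,0.74,0.9,beta
t2dm,,,0.785,0.68,0.89,beta
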