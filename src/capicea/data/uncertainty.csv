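name,kind,mean,lower,upper
hr_fatal_chd_male,hazard_ratio,2.03,-0.11,4.41
hr_fatal_chd_female,hazard_ratio,2.54,-0.85,6.42
hr_fatal_stroke_male,hazard_ratio,2.00,-1.90,5.13
hr_fatal_stroke_female,hazard_ratio,2.04,-0.71,5.04
risk_fatal_chd_male_intervention,risk_pct,6.06,3.92,8.50
risk_fatal_chd_female_intervention,risk_pct,3.28,2.21,4.27
risk_fatal_stroke_male_intervention,risk_pct,0.83,0.76,0.92
risk_fatal_stroke_female_intervention,risk_pct,0.62,0.54,0.71
risk_fatal_chd_male_comparator,risk_pct,8.74,5.57,11.66
risk_fatal_chd_female_comparator,risk_pct,4.78,3.02,6.41
risk_fatal_stroke_male_comparator,risk_pct,1.13,0.94,1.29
risk_fatal_stroke_female_comparator,risk_pct,0.82,0.73,0.94
cost_intervention,cost_zar,5950,5401,6533
cost_comparator,cost_zar,4946,4467,5392
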