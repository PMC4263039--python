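arm,outcome,sex,mean_risk_pct,se_pct
intervention,CHD,male,9.92,0.93
comparator,CHD,male,13.05,1.23
intervention,CHD,female,5.36,0.49
comparator,CHD,female,7.11,0.70
intervention,fatal_CHD,male,6.06,0.60
comparator,fatal_CHD,male,8.74,0.96
intervention,fatal_CHD,female,3.28,0.32
comparator,fatal_CHD,female,4.78,0.55
intervention,stroke,male,6.40,0.21
comparator,stroke,male,7.12,0.26
intervention,stroke,female,4.54,0.13
comparator,stroke,female,5.05,0.20
intervention,fatal_stroke,male,0.83,0.03
comparator,fatal_stroke,male,1.13,0.05
intervention,fatal_stroke,female,0.62,0.03
comparator,fatal_stroke,female,0.82,0.03
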