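scenario,pollutant,endpoint,cases,cost_musd
typical_controlled,PM,all_cause_mortality,1.752,20.6
typical_controlled,PM,asthma,2.722,0.0
typical_controlled,PM,diabetes,5.378,0.1
typical_controlled,PM,ischemic_heart_disease,0.105,0.0
typical_controlled,PM,respiratory_tract_cancer,0.069,0.0
typical_controlled,PM,stroke,0.267,0.0
typical_controlled,NOx,all_cause_mortality,3.216,37.8
typical_controlled,NOx,asthma,30.820,0.1
typical_controlled,NOx,ischemic_heart_disease,0.339,0.0
typical_controlled,SO2,all_cause_mortality,0.160,1.9
typical_controlled,SO2,ischemic_heart_disease,0.052,0.0
typical_controlled,CO,all_cause_mortality,0.003,0.0
typical_controlled,CO,ischemic_heart_disease,0.003,0.0
typical_uncontrolled,PM,all_cause_mortality,4.518,53.0
typical_uncontrolled,PM,asthma,7.050,0.0
typical_uncontrolled,PM,diabetes,13.854,0.2
typical_uncontrolled,PM,ischemic_heart_disease,0.272,0.0
typical_uncontrolled,PM,respiratory_tract_cancer,0.179,0.0
typical_uncontrolled,PM,stroke,0.693,0.0
typical_uncontrolled,NOx,all_cause_mortality,3.482,40.9
typical_uncontrolled,NOx,asthma,33.386,0.1
typical_uncontrolled,NOx,ischemic_heart_disease,0.367,0.0
typical_uncontrolled,SO2,all_cause_mortality,0.224,2.6
typical_uncontrolled,SO2,ischemic_heart_disease,0.073,0.0
typical_uncontrolled,CO,all_cause_mortality,0.003,0.0
typical_uncontrolled,CO,ischemic_heart_disease,0.003,0.0
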