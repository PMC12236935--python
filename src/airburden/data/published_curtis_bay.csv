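scenario,pollutant,endpoint,cases,cost_musd
typical_controlled,PM,all_cause_mortality,0.049,0.6
typical_controlled,PM,asthma,0.076,0.0
typical_controlled,PM,diabetes,0.150,0.0
typical_controlled,PM,ischemic_heart_disease,0.003,0.0
typical_controlled,PM,respiratory_tract_cancer,0.002,0.0
typical_controlled,PM,stroke,0.007,0.0
typical_controlled,NOx,all_cause_mortality,0.294,3.4
typical_controlled,NOx,asthma,2.750,0.0
typical_controlled,NOx,ischemic_heart_disease,0.030,0.0
typical_controlled,SO2,all_cause_mortality,0.028,0.3
typical_controlled,SO2,ischemic_heart_disease,0.009,0.0
typical_controlled,CO,all_cause_mortality,0.002,0.0
typical_controlled,CO,ischemic_heart_disease,0.002,0.0
typical_uncontrolled,PM,all_cause_mortality,3.128,36.7
typical_uncontrolled,PM,asthma,4.839,0.0
typical_uncontrolled,PM,diabetes,9.561,0.1
typical_uncontrolled,PM,ischemic_heart_disease,0.187,0.0
typical_uncontrolled,PM,respiratory_tract_cancer,0.123,0.0
typical_uncontrolled,PM,stroke,0.476,0.0
typical_uncontrolled,NOx,all_cause_mortality,0.596,7.0
typical_uncontrolled,NOx,asthma,5.687,0.0
typical_uncontrolled,NOx,ischemic_heart_disease,0.063,0.0
typical_uncontrolled,SO2,all_cause_mortality,0.085,1.0
typical_uncontrolled,SO2,ischemic_heart_disease,0.027,0.0
typical_uncontrolled,CO,all_cause_mortality,0.002,0.0
typical_uncontrolled,CO,ischemic_heart_disease,0.002,0.0
max_controlled,PM,all_cause_mortality,0.107,1.3
max_controlled,PM,asthma,0.166,0.0
max_controlled,PM,diabetes,0.329,0.0
max_controlled,PM,ischemic_heart_disease,0.006,0.0
max_controlled,PM,respiratory_tract_cancer,0.004,0.0
max_controlled,PM,stroke,0.016,0.0
max_controlled,NOx,all_cause_mortality,0.713,8.4
max_controlled,NOx,asthma,6.798,0.0
max_controlled,NOx,ischemic_heart_disease,0.075,0.0
max_controlled,SO2,all_cause_mortality,0.067,0.8
max_controlled,SO2,ischemic_heart_disease,0.021,0.0
max_controlled,CO,all_cause_mortality,0.005,0.1
max_controlled,CO,ischemic_heart_disease,0.005,0.0
max_uncontrolled,PM,all_cause_mortality,7.450,87.5
max_uncontrolled,PM,asthma,11.525,0.0
max_uncontrolled,PM,diabetes,22.744,0.3
max_uncontrolled,PM,ischemic_heart_disease,0.445,0.0
max_uncontrolled,PM,respiratory_tract_cancer,0.293,0.0
max_uncontrolled,PM,stroke,1.133,0.1
max_uncontrolled,NOx,all_cause_mortality,1.426,16.7
max_uncontrolled,NOx,asthma,13.590,0.1
max_uncontrolled,NOx,ischemic_heart_disease,0.149,0.0
max_uncontrolled,SO2,all_cause_mortality,0.203,2.4
max_uncontrolled,SO2,ischemic_heart_disease,0.064,0.0
max_uncontrolled,CO,all_cause_mortality,0.005,0.1
max_uncontrolled,CO,ischemic_heart_disease,0.005,0.0
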