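year,pollutant,endpoint,cases,cost_musd
2014,PM,all_cause_mortality,0.721,8.5
2014,PM,asthma,1.091,0.0
2014,PM,diabetes,2.219,0.0
2014,PM,ischemic_heart_disease,0.046,0.0
2014,PM,respiratory_tract_cancer,0.035,0.0
2014,PM,stroke,0.107,0.0
2014,NOx,all_cause_mortality,4.156,48.8
2014,NOx,asthma,38.643,0.2
2014,NOx,ischemic_heart_disease,0.469,0.0
2014,SO2,all_cause_mortality,0.296,3.5
2014,SO2,ischemic_heart_disease,0.101,0.0
2014,CO,all_cause_mortality,0.001,0.0
2014,CO,ischemic_heart_disease,0.001,0.0
2017,PM,all_cause_mortality,0.889,10.4
2017,PM,asthma,1.347,0.0
2017,PM,diabetes,2.729,0.0
2017,PM,ischemic_heart_disease,0.053,0.0
2017,PM,respiratory_tract_cancer,0.038,0.0
2017,PM,stroke,0.130,0.0
2017,NOx,all_cause_mortality,4.306,50.5
2017,NOx,asthma,40.257,0.2
2017,NOx,ischemic_heart_disease,0.452,0.0
2017,SO2,all_cause_mortality,0.310,3.6
2017,SO2,ischemic_heart_disease,0.098,0.0
2017,CO,all_cause_mortality,0.001,0.0
2017,CO,ischemic_heart_disease,0.001,0.0
2020,PM,all_cause_mortality,0.777,9.1
2020,PM,asthma,1.224,0.0
2020,PM,diabetes,2.382,0.0
2020,PM,ischemic_heart_disease,0.043,0.0
2020,PM,respiratory_tract_cancer,0.030,0.0
2020,PM,stroke,0.117,0.0
2020,NOx,all_cause_mortality,3.697,43.4
2020,NOx,asthma,36.044,0.1
2020,NOx,ischemic_heart_disease,0.363,0.0
2020,SO2,all_cause_mortality,0.314,3.7
2020,SO2,ischemic_heart_disease,0.092,0.0
2020,CO,all_cause_mortality,0.001,0.0
2020,CO,ischemic_heart_disease,0.001,0.0
2023,PM,all_cause_mortality,0.894,10.5
2023,PM,asthma,1.378,0.0
2023,PM,diabetes,2.748,0.0
2023,PM,ischemic_heart_disease,0.053,0.0
2023,PM,respiratory_tract_cancer,0.035,0.0
2023,PM,stroke,0.135,0.0
2023,NOx,all_cause_mortality,3.189,37.4
2023,NOx,asthma,30.364,0.1
2023,NOx,ischemic_heart_disease,0.334,0.0
2023,SO2,all_cause_mortality,0.174,2.0
2023,SO2,ischemic_heart_disease,0.055,0.0
2023,CO,all_cause_mortality,0.001,0.0
2023,CO,ischemic_heart_disease,0.001,0.0
2024,PM,all_cause_mortality,1.587,18.6
2024,PM,asthma,2.469,0.0
2024,PM,diabetes,4.874,0.1
2024,PM,ischemic_heart_disease,0.095,0.0
2024,PM,respiratory_tract_cancer,0.063,0.0
2024,PM,stroke,0.242,0.0
2024,NOx,all_cause_mortality,2.876,33.8
2024,NOx,asthma,27.296,0.1
2024,NOx,ischemic_heart_disease,0.300,0.0
2024,SO2,all_cause_mortality,0.105,1.2
2024,SO2,ischemic_heart_disease,0.033,0.0
2024,CO,all_cause_mortality,0.001,0.0
2024,CO,ischemic_heart_disease,0.001,0.0
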