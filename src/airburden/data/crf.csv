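pollutant,endpoint,rr,increment_ugm3,source_label
PM,all_cause_mortality,1.06,10,synthetic stand-in for long-term PM2.5 mortality RR
PM,asthma,1.10,10,synthetic stand-in
PM,diabetes,1.10,10,synthetic stand-in
PM,ischemic_heart_disease,1.08,10,synthetic stand-in
PM,respiratory_tract_cancer,1.09,10,synthetic stand-in
PM,stroke,1.06,10,synthetic stand-in
NOx,all_cause_mortality,1.02,10,synthetic stand-in for NO2 mortality RR
NOx,asthma,1.05,10,synthetic stand-in
NOx,ischemic_heart_disease,1.03,10,synthetic stand-in
SO2,all_cause_mortality,1.02,10,synthetic stand-in
SO2,ischemic_heart_disease,1.02,10,synthetic stand-in
CO,all_cause_mortality,1.002,1000,synthetic stand-in (RR per mg/m3)
CO,ischemic_heart_disease,1.002,1000,synthetic stand-in (RR per mg/m3)
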