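endpoint,value_per_case_usd,dollar_year,kind
all_cause_mortality,11740000,2025,VSL
asthma,3700,2025,cost_of_illness
diabetes,20000,2025,cost_of_illness
ischemic_heart_disease,50000,2025,cost_of_illness
respiratory_tract_cancer,100000,2025,cost_of_illness
stroke,40000,2025,cost_of_illness
copd,30000,2025,cost_of_illness
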