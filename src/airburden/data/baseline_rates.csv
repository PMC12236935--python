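endpoint,y0_per_100k,year,source_label
all_cause_mortality,950.0,2024,synthetic stand-in for US crude all-cause mortality
asthma,400.0,2024,synthetic stand-in for asthma incidence
diabetes,620.0,2024,synthetic stand-in for diabetes incidence
ischemic_heart_disease,210.0,2024,synthetic stand-in for IHD incidence
respiratory_tract_cancer,55.0,2024,synthetic stand-in for respiratory tract cancer incidence
stroke,250.0,2024,synthetic stand-in for stroke incidence
copd,500.0,2024,synthetic stand-in for COPD prevalence
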