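pollutant,factor_kg_per_ton,basis,source_label
PM,2.33,uncontrolled,synthetic stand-in for AP-42 medical waste incinerator factor
NOx,1.78,uncontrolled,synthetic stand-in for AP-42 medical waste incinerator factor
SO2,1.09,uncontrolled,synthetic stand-in for AP-42 medical waste incinerator factor
CO,1.48,uncontrolled,synthetic stand-in for AP-42 medical waste incinerator factor
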