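pollutant,efficiency,technologies
PM,0.984,FF|ACI
NOx,0.50,retrofit
SO2,0.67,DSI
CO,0.0,
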