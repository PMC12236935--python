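year,index
2014,236.7
2015,237.0
2016,240.0
2017,245.1
2018,251.1
2019,255.7
2020,258.8
2021,271.0
2022,292.7
2023,304.7
2024,313.7
2025,321.5
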