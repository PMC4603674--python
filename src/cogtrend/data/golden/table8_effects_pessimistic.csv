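year,e_base,e_minor,e_pop,e_pm,e_total
2015,0.02,0.13,-0.09,<0.01,0.06
2020,0.05,0.34,-0.22,0.03,0.20
2025,0.07,0.55,-0.35,0.09,0.36
2030,0.10,0.76,-0.49,0.17,0.54
2035,0.13,0.97,-0.63,0.28,0.75
2040,0.16,1.19,-0.78,0.42,0.98
2045,0.19,1.40,-0.93,0.58,1.24
2050,0.21,1.61,-1.08,0.78,1.52
2055,0.24,1.82,-1.23,0.99,1.83
2060,0.27,2.03,-1.36,1.22,2.16
per decade,0.06,0.42,-0.28,0.25,0.45
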