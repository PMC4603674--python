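year,e_base,e_minor,e_pop,e_pm,e_total
2015,0.14,0.11,-0.09,<0.01,0.17
2020,0.37,0.30,-0.22,0.03,0.48
2025,0.60,0.48,-0.35,0.07,0.81
2030,0.84,0.67,-0.49,0.14,1.16
2035,1.07,0.86,-0.63,0.23,1.53
2040,1.30,1.04,-0.78,0.35,1.91
2045,1.53,1.23,-0.93,0.49,2.32
2050,1.77,1.41,-1.08,0.65,2.75
2055,2.00,1.60,-1.23,0.83,3.20
2060,2.23,1.79,-1.36,1.03,3.68
per decade,0.46,0.37,-0.28,0.21,0.77
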