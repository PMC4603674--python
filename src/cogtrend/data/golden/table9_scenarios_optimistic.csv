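year,Standard,Best Case,Worst Case
2012,99.50,99.50,99.50
2015,99.66,99.91,99.55
2020,99.98,100.61,99.65
2025,100.31,101.31,99.75
2030,100.65,102.01,99.84
2035,101.02,102.70,99.93
2040,101.41,103.38,100.01
2045,101.81,104.07,100.10
2050,102.24,104.75,100.18
2055,102.70,105.44,100.27
2060,103.17,106.14,100.36
Total increase,3.68,6.64,0.87
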