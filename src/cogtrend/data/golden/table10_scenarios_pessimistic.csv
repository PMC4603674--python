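year,Standard,Best Case,Worst Case
2012,99.50,99.50,99.50
2015,99.56,100.01,99.43
2020,99.70,100.88,99.32
2025,99.86,101.74,99.22
2030,100.04,102.60,99.11
2035,100.25,103.45,98.99
2040,100.48,104.30,98.87
2045,100.73,105.15,98.75
2050,101.01,105.99,98.63
2055,101.32,106.85,98.51
2060,101.66,107.71,98.40
Total increase,2.16,8.21,-1.09
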