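year,White,Black,Hispanic,Asian,Population
2012,102.28,91.14,93.60,105.05,99.50
2015,102.42,91.57,94.06,105.55,99.66
2020,102.65,92.29,94.83,106.38,99.98
2025,102.88,93.01,95.60,107.21,100.31
2030,103.11,93.73,96.37,108.05,100.65
2035,103.34,94.45,97.14,108.88,101.02
2040,103.58,95.17,97.91,109.72,101.41
2045,103.81,95.89,98.68,110.55,101.81
2050,104.04,96.61,99.45,111.38,102.24
2055,104.27,97.33,100.22,112.22,102.70
2060,104.51,98.05,100.99,113.05,103.17
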