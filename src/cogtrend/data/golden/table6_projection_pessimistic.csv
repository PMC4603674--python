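year,White,Black,Hispanic,Asian,Population
2012,102.28,91.14,93.60,105.05,99.50
2015,102.29,91.44,93.97,105.64,99.56
2020,102.32,91.93,94.59,106.64,99.70
2025,102.35,92.42,95.21,107.64,99.86
2030,102.38,92.92,95.84,108.64,100.04
2035,102.41,93.41,96.46,109.63,100.25
2040,102.43,93.90,97.08,110.63,100.48
2045,102.46,94.40,97.70,111.63,100.73
2050,102.49,94.89,98.32,112.63,101.01
2055,102.52,95.38,98.95,113.62,101.32
2060,102.55,95.88,99.57,114.62,101.66
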