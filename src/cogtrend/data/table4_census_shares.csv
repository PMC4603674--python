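year,White,Black,Hispanic,Asian,Sum
2012,62.98,12.34,16.89,4.98,97.19
2015,61.75,12.40,17.76,5.12,97.03
2020,59.69,12.51,19.10,5.46,96.77
2025,57.61,12.60,20.49,5.81,96.51
2030,55.46,12.68,21.94,6.15,96.23
2035,53.26,12.75,23.44,6.49,95.94
2040,51.02,12.83,24.97,6.81,95.63
2045,48.78,12.92,26.48,7.12,95.30
2050,46.61,13.00,27.95,7.40,94.96
2055,44.53,13.08,29.34,7.65,94.61
2060,42.58,13.16,30.64,7.88,94.26
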