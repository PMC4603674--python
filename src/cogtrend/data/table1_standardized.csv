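cohort,White,Black,Hispanic,Asian,Average
1978/80,100.00,81.46,86.92,100.89,97.27
1982/84,99.99,86.31,88.34,99.98,97.47
1986/88,100.75,90.03,90.35,101.73,98.65
1990,101.60,90.94,91.25,100.70,99.13
1992,102.32,88.97,92.56,102.67,99.63
1994,102.07,90.01,90.63,101.60,99.24
1996,102.19,90.20,91.36,100.11,99.37
1999,102.43,89.06,92.57,102.87,99.59
2004,101.69,89.56,90.53,102.06,98.62
2008,102.29,90.45,92.30,103.92,98.68
2012,102.28,91.14,93.60,105.05,98.88
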