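subject,period,White,Black,Hispanic,Asian
Mathematics,1978/80-2012,0.0914,0.1636,0.1990,0.1186
Mathematics,1992-2012,0.0211,0.0719,0.0829,0.1166
Reading,1978/80-2012,0.0016,0.1243,0.1089,0.2150
Reading,1992-2012,-0.0098,0.1255,0.1659,0.2824
Average,1978/80-2012,0.0465,0.1439,0.1539,0.1668
Average,1992-2012,0.0056,0.0987,0.1244,0.1995
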