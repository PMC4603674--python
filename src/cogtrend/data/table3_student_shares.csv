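subject,year,White,Black,Hispanic,Asian,Sum
Mathematics,1978,83,12,4,1,100
Mathematics,1982,81,13,5,2,101
Mathematics,1986,78,14,5,2,99
Mathematics,1990,73,16,7,3,99
Mathematics,1992,75,15,7,3,100
Mathematics,1994,72,15,9,2,98
Mathematics,1996,71,15,9,3,98
Mathematics,1999,71,15,10,4,100
Mathematics,2004,68,12,14,4,98
Mathematics,2008,59,14,19,5,97
Mathematics,2012,56,13,22,6,97
Reading,1980,83,12,4,1,100
Reading,1984,77,14,7,2,100
Reading,1988,77,15,6,2,100
Reading,1990,74,16,7,3,100
Reading,1992,75,15,8,3,101
Reading,1994,72,15,8,3,98
Reading,1996,72,15,9,3,99
Reading,1999,72,14,9,4,99
Reading,2004,67,12,15,4,98
Reading,2008,59,15,18,5,97
Reading,2012,56,14,22,6,98
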