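# synthetic stand-in membership list: Wu & Eisen 2008 (AMPHORA), 31 USCGs
# one COG identifier per line
COG0008
COG0012
COG0013
COG0016
COG0017
COG0018
COG0024
COG0030
COG0048
COG0049
COG0052
COG0060
COG0072
COG0080
COG0081
COG0087
COG0088
COG0090
COG0091
COG0092
COG0093
COG0130
COG0143
COG0150
COG0180
COG0216
COG0233
COG0244
COG0290
COG0343
COG0361
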