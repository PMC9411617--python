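# synthetic stand-in membership list: Ciccarelli et al. 2006, 31 USCGs
# one COG identifier per line
COG0012
COG0016
COG0018
COG0048
COG0049
COG0052
COG0080
COG0081
COG0087
COG0088
COG0090
COG0091
COG0092
COG0093
COG0094
COG0096
COG0097
COG0098
COG0099
COG0100
COG0102
COG0103
COG0124
COG0172
COG0184
COG0185
COG0186
COG0197
COG0200
COG0201
COG0202
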