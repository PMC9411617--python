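# synthetic stand-in membership list: Lan et al. 2016, 73 USCGs
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
COG0050
COG0052
COG0060
COG0072
COG0080
COG0081
COG0085
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
COG0130
COG0143
COG0150
COG0172
COG0180
COG0184
COG0185
COG0186
COG0197
COG0200
COG0201
COG0202
COG0215
COG0216
COG0228
COG0231
COG0233
COG0238
COG0244
COG0250
COG0255
COG0256
COG0261
COG0264
COG0267
COG0268
COG0290
COG0291
COG0292
COG0335
COG0343
COG0361
COG0495
COG0522
COG0525
COG0532
COG0533
COG0541
COG0552
COG0691
COG1093
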