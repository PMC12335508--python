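index,D,BP,FP,BCF,KOC,P,MV
M1,0.8539,0.6792,0.8008,0.6609,0.6798,0.9175,0.8794
M2,0.8554,0.7137,0.8462,0.7028,0.7222,0.9342,0.8657
NM1,0.8545,0.7257,0.8622,0.6976,0.7170,0.9391,0.8681
NM2,0.8615,0.7210,0.8695,0.7398,0.7583,0.9367,0.8373
NSS,0.8032,0.7985,0.9001,0.6198,0.6422,0.9404,0.9767
NH,0.8266,0.7422,0.8703,0.6708,0.6908,0.9441,0.9240
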