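index,property,n,A,B,C,R,R2,F,p,note
M1,D,10,2.0622,-0.0208,0.0001,0.8539,0.7292,9.423,0.01,
M1,BP,10,603.7442,-3.7566,0.0229,0.6792,0.4612,2.9978,0.11,
M1,FP,10,479.0312,-5.3411,0.0281,0.8008,0.6412,6.256,0.02,
M1,BCF,10,568.9568,-10.9117,0.0509,0.6609,0.4367,2.713,0.13,
M1,KOC,10,600.5683,-11.5314,0.0539,0.6798,0.4621,3.0006,0.11,
M1,P,10,34.9526,-0.2498,0.0023,0.9175,0.8419,18.63,0.001,
M1,MV,10,7.7104,3.2116,-0.0058,0.8794,0.7733,10.9397,0.005,
M2,D,10,1.5423,-0.0098,0.0001,0.8554,0.7316,9.54,0.01,
M2,BP,10,565.0199,-2.608,0.0148,0.7137,0.5093,3.63,0.08,
M2,FP,10,413.4675,-3.6374,0.0176,0.8462,0.7161,8.82,0.01,
M2,BCF,10,416.8889,-7.2842,0.0307,0.7028,0.4940,3.42,0.09,
M2,KOC,10,438.5572,-7.6750,0.0325,0.7220,0.5213,3.81,0.07,
M2,P,10,32.1071,-0.1474,0.0014,0.9342,0.8727,23.99,0.007,
M2,MV,10,77.6323,2.1015,-0.0023,0.8657,0.7495,10.47,0.007,
NM1,D,10,1.5641,-0.0051,0.0000,0.8545,0.7302,9.47,0.01,
NM1,BP,10,669.01,-2.1284,0.0052,0.7257,0.5266,3.89,0.07,
NM1,FP,10,451.8066,-2.1361,0.0050,0.8622,0.7434,10.13,0.08,
NM1,BCF,10,330.5274,-3.0644,0.0066,0.6976,0.4876,3.32,0.09,
NM1,KOC,10,348.1879,-3.1703,0.0070,0.7170,0.5141,3.70,0.08,
NM1,P,10,32.4871,-0.0750,0.0004,0.9391,0.8820,25.66,0.0006,
NM1,MV,10,112.3116,0.7657,-0.0002,0.8681,0.7535,10.70,0.07,
NM2,D,10,1.1889,-0.0007,0.0000,0.8615,0.7421,10.07,0.0008,
NM2,BP,10,532.0131,-0.3437,0.0004,0.7210,0.5199,3.78,0.07,
NM2,FP,10,339.3478,-0.4302,0.0004,0.8695,0.7561,10.84,0.007,
NM2,BCF,10,225.1993,-0.7842,0.0006,0.7398,0.5473,4.23,0.06,
NM2,KOC,10,235.3215,-0.8216,0.0007,0.7583,0.575,4.73,0.05,
NM2,P,10,30.9501,-0.0155,0.0000,0.9367,0.8773,25.03,0.0006,
NM2,MV,10,177.9734,0.1439,-0.0000,0.8373,0.7010,8.21,0.01,
NSS,D,10,1.5038,-0.0306,0.0005,0.8032,0.6451,6.36,0.02,
NSS,BP,10,826.218,-22.7316,0.3414,0.7985,0.6377,6.15,0.02,
NSS,FP,10,524.2793,-18.1217,0.2725,0.9001,0.8102,14.94,0.003,sign of B not printed in the source coefficient block
NSS,BCF,10,247.5362,-15.3273,0.2329,0.6198,0.3841,2.18,0.18,
NSS,KOC,10,267.1751,-16.5314,0.2510,0.6422,0.4124,2.46,0.15,
NSS,P,10,24.2235,-0.1429,0.0120,0.9404,0.8884,26.77,0.0005,
NSS,MV,10,-10.7559,10.8872,-0.0724,0.8767,0.7686,11.62,0.006,
NH,D,10,3.1426,-0.9249,0.1032,0.8266,0.6823,7.55,0.02,
NH,BP,10,1395.9975,-410.6739,44.2795,0.7422,0.5509,4.29,0.06,
NH,FP,10,1020.7927,-345.6808,37.2199,0.8703,0.7574,10.93,0.007,
NH,BCF,10,789.8855,-345.4214,37.1511,0.6708,0.4499,2.86,0.12,
NH,KOC,10,837.322,-366.4765,39.4514,0.6908,0.4772,3.19,0.10,
NH,P,10,52.5421,-14.6256,2.2526,0.9441,0.8913,28.69,0.0004,
NH,MV,10,-121.4233,112.4479,-5.6469,0.9240,0.8537,20.42,0.001,
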