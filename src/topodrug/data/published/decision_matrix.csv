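drug,M1,M2,NM1,NM2,NSS,NH
metoprolol,0.230644,0.218443,0.220074,0.195706,0.233787,0.267839
atenolol,0.236135,0.223352,0.200292,0.181040,0.210465,0.236886
bisoprolol,0.280068,0.262623,0.264583,0.231456,0.282706,0.320269
propranolol,0.252610,0.252805,0.254692,0.250706,0.257028,0.257100
sotalol,0.236135,0.225806,0.223783,0.211289,0.232487,0.256468
amiodarone,0.428339,0.451613,0.454984,0.492245,0.436533,0.408075
carvedilol,0.422847,0.441795,0.445093,0.471620,0.443521,0.404916
flecainide,0.384407,0.375526,0.374620,0.368038,0.354459,0.359434
propafenone,0.318508,0.314166,0.316510,0.297455,0.326506,0.319638
timolol,0.285559,0.282258,0.284365,0.281414,0.285469,0.275419
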