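point,M1,M2,NM1,NM2,NSS,NH
best,0.072977,0.075045,0.074858,0.076443,0.074693,0.071504
worst,0.039295,0.036299,0.032954,0.028114,0.035444,0.041508
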