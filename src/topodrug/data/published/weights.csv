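criterion,weight
M1,0.170372
M2,0.166171
NM1,0.164530
NM2,0.155294
NSS,0.168411
NH,0.175222
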