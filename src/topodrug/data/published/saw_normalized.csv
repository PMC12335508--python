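drug,M1,M2,NM1,NM2,NSS,NH
metoprolol,0.538462,0.483696,0.483696,0.397579,0.527116,0.656347
atenolol,0.551282,0.494565,0.440217,0.367784,0.474533,0.580495
bisoprolol,0.653846,0.581522,0.581522,0.470205,0.637413,0.784830
propranolol,0.589744,0.559783,0.559783,0.509311,0.579516,0.630031
sotalol,0.551282,0.500000,0.491848,0.429236,0.524185,0.628483
amiodarone,1.000000,1.000000,1.000000,1.000000,0.984243,1.000000
carvedilol,0.987179,0.978261,0.978261,0.958101,1.000000,0.992260
flecainide,0.897436,0.831522,0.823370,0.747672,0.799194,0.880805
propafenone,0.743590,0.695652,0.695652,0.604283,0.736167,0.783282
timolol,0.666667,0.625000,0.625000,0.571695,0.643642,0.674923
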