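drug,L_plus,L_minus,closeness,rank
amiodarone,0.001176,0.095272,0.987807,1
carvedilol,0.004093,0.092281,0.957534,2
flecainide,0.032563,0.063897,0.662416,3
propafenone,0.054170,0.041973,0.436569,4
timolol,0.067026,0.028973,0.301809,5
bisoprolol,0.072222,0.025681,0.262307,6
propranolol,0.078530,0.017827,0.185013,7
sotalol,0.088316,0.008057,0.083599,8
metoprolol,0.090009,0.007786,0.079616,9
atenolol,0.095094,0.001242,0.012890,10
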