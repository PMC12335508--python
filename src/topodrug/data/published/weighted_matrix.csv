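drug,M1,M2,NM1,NM2,NSS,NH
metoprolol,0.039295,0.036299,0.036209,0.030392,0.039372,0.046931
atenolol,0.040231,0.037115,0.032954,0.028114,0.035444,0.041508
bisoprolol,0.047716,0.043640,0.043532,0.035944,0.047611,0.056118
propranolol,0.043038,0.042009,0.041904,0.038933,0.043286,0.045050
sotalol,0.040231,0.037522,0.036819,0.032812,0.039153,0.044939
amiodarone,0.072977,0.075045,0.074858,0.076443,0.073517,0.071504
carvedilol,0.072041,0.073414,0.073231,0.073240,0.074693,0.070950
flecainide,0.065492,0.062402,0.061636,0.057154,0.059694,0.062981
propafenone,0.054265,0.052205,0.052075,0.046193,0.054987,0.056008
timolol,0.048651,0.046903,0.046787,0.043702,0.048076,0.048259
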