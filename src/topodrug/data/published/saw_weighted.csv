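drug,M1,M2,NM1,NM2,NSS,NH
metoprolol,0.091739,0.080376,0.079582,0.061742,0.088772,0.115006
atenolol,0.093923,0.082182,0.072429,0.057115,0.079917,0.101716
bisoprolol,0.111397,0.096632,0.095678,0.073020,0.107347,0.137519
propranolol,0.100476,0.093020,0.092101,0.079093,0.097597,0.110395
sotalol,0.093923,0.083086,0.080924,0.066658,0.088278,0.110124
amiodarone,0.170372,0.166171,0.164530,0.155294,0.165757,0.175222
carvedilol,0.168188,0.162559,0.160953,0.148787,0.168411,0.173866
flecainide,0.152898,0.138175,0.135469,0.116109,0.134593,0.154336
propafenone,0.126687,0.115597,0.114456,0.093842,0.123979,0.137248
timolol,0.113581,0.103857,0.102831,0.088781,0.108396,0.118261
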