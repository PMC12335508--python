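drug,score,rank
amiodarone,0.997346,1
carvedilol,0.982764,2
flecainide,0.831580,3
propafenone,0.711808,4
timolol,0.635708,5
bisoprolol,0.621594,6
propranolol,0.572682,7
sotalol,0.522993,8
metoprolol,0.517218,9
atenolol,0.487281,10
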