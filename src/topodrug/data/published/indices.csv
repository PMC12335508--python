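drug,M1,M2,NM1,NM2,NSS,NH
metoprolol,84,89,178,427,28.77,4.24
atenolol,86,91,162,395,25.9,3.75
bisoprolol,102,107,214,505,34.79,5.07
propranolol,92,103,206,547,31.63,4.07
sotalol,86,92,181,461,28.21,3.69
amiodarone,156,184,368,1074,53.72,6.46
carvedilol,154,180,360,1029,53.58,6.41
flecainide,140,153,303,803,46.42,5.69
propafenone,116,128,256,649,40.18,5.56
timolol,104,115,230,614,35.13,4.36
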