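drug,D,BP,FP,BCF,KOC,P,MV
metoprolol,1.00,398.60,194.90,1.00,1.00,30.60,258.70
atenolol,1.10,508.00,261.10,1.00,1.00,29.40,236.70
bisoprolol,1.00,445.00,222.90,1.00,1.00,36.70,315.00
propranolol,1.10,434.90,216.80,1.25,1.00,31.30,237.20
sotalol,1.20,443.30,221.90,1.00,1.00,28.60,219.70
amiodarone,1.60,635.10,337.90,214.87,223.42,57.20,408.20
carvedilol,1.30,655.20,350.10,1.51,8.15,47.40,325.10
flecainide,1.30,434.90,216.80,1.00,1.07,34.80,322.10
propafenone,1.10,519.60,268.00,1.00,1.61,39.80,311.40
timolol,1.20,487.20,248.50,1.00,1.00,32.60,258.50
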