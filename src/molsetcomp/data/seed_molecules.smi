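CC(=O)Oc1ccccc1C(=O)O aspirin
Cn1cnc2c1c(=O)n(C)c(=O)n2C caffeine
CC(=O)Nc1ccc(O)cc1 paracetamol
CC(C)Cc1ccc(cc1)C(C)C(=O)O ibuprofen
COc1ccc2cc(ccc2c1)C(C)C(=O)O naproxen
CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1 ketoprofen
OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl diclofenac
c1ccccc1 benzene
Cc1ccccc1 toluene
Oc1ccccc1 phenol
Nc1ccccc1 aniline
c1ccncc1 pyridine
CN1CCCC1c1cccnc1 nicotine
CCO ethanol
CC(=O)O acetic_acid
NCC(=O)O glycine
CC(N)C(=O)O alanine
OCC(N)C(=O)O serine
NC(Cc1ccccc1)C(=O)O phenylalanine
OCC1OC(O)C(O)C(O)C1O glucose
C1CCCCC1 cyclohexane
OC1CCCCC1 cyclohexanol
c1ccc2ccccc2c1 naphthalene
c1ccc2[nH]ccc2c1 indole
c1c[nH]cn1 imidazole
c1ccoc1 furan
c1ccsc1 thiophene
C1COCCN1 morpholine
C1CCNCC1 piperidine
C1CNCCN1 piperazine
NC(=O)c1ccccc1 benzamide
OC(=O)c1ccccc1 benzoic_acid
OC(=O)c1ccccc1O salicylic_acid
NS(=O)(=O)c1ccc(N)cc1 sulfanilamide
CCN(CC)CCOC(=O)c1ccc(N)cc1 procaine
CCN(CC)CC(=O)Nc1c(C)cccc1C lidocaine
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1 atenolol
CC(C)NCC(O)COc1cccc2ccccc12 propranolol
COCCc1ccc(OCC(O)CNC(C)C)cc1 metoprolol
CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O warfarin
CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21 diazepam
CNC(C)C(O)c1ccccc1 ephedrine
CC(N)Cc1ccccc1 amphetamine
NCCc1ccc(O)c(O)c1 dopamine
NCCc1c[nH]c2ccc(O)cc12 serotonin
NCCc1c[nH]cn1 histamine
CNCC(O)c1ccc(O)c(O)c1 adrenaline
CC(=O)NCCc1c[nH]c2ccc(OC)cc12 melatonin
NC(=O)c1cccnc1 nicotinamide
NNC(=O)c1ccncc1 isoniazid
NC(=O)c1cnccn1 pyrazinamide
Cc1ncc([N+](=O)[O-])n1CCO metronidazole
Cn1c(=O)c2[nH]cnc2n(C)c1=O theophylline
O=c1cc[nH]c(=O)[nH]1 uracil
Nc1ncnc2[nH]cnc12 adenine
Nc1cc[nH]c(=O)n1 cytosine
Cc1c[nH]c(=O)[nH]c1=O thymine
CC(C)C1CCC(C)CC1O menthol
CC(=C)C1CCC(C)=CC1 limonene
CC1(C)C2CCC1(C)C(=O)C2 camphor
COc1cc(C=O)ccc1O vanillin
COc1cc(CC=C)ccc1O eugenol
O=c1ccc2ccccc2o1 coumarin
c1ccc2ncccc2c1 quinoline
c1ccc2cnccc2c1 isoquinoline
c1ccc(-c2ccccc2)cc1 biphenyl
C1CCC2(C1)CCCC2 spiro44nonane
C1C2CC3CC1CC(C2)C3 adamantane
NCCS(=O)(=O)O taurine
OC(=O)CC(O)(CC(=O)O)C(=O)O citric_acid
NC(N)=O urea
CC(C)=O acetone
CC#N acetonitrile
C=CC=C butadiene
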