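name,smiles
aspirin,CC(=O)Oc1ccccc1C(=O)O
paracetamol,CC(=O)Nc1ccc(O)cc1
ibuprofen,CC(C)Cc1ccc(C(C)C(=O)O)cc1
naproxen,COc1ccc2cc(C(C)C(=O)O)ccc2c1
caffeine,Cn1cnc2c1c(=O)n(C)c(=O)n2C
diclofenac,OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl
indomethacin,COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1
celecoxib,Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1
atenolol,CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
propranolol,CC(C)NCC(O)COc1cccc2ccccc12
metoprolol,COCCc1ccc(OCC(O)CNC(C)C)cc1
amlodipine,CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl
atorvastatin,CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CCC(O)CC(O)CC(=O)O
simvastatin,CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21
warfarin,CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
metformin,CN(C)C(=N)NC(N)=N
glibenclamide,COc1ccc(Cl)cc1C(=O)NCCc1ccc(S(=O)(=O)NC(=O)NC2CCCCC2)cc1
omeprazole,COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1
ranitidine,CNC(=C[N+](=O)[O-])NCCSCc1ccc(CN(C)C)o1
loratadine,CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1
cetirizine,OC(=O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1
diphenhydramine,CN(C)CCOC(c1ccccc1)c1ccccc1
amoxicillin,CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O
ciprofloxacin,OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O
azithromycin,CCC1OC(=O)C(C)C(OC2CC(C)(OC)C(O)C(C)O2)C(C)C(OC2OC(C)CC(N(C)C)C2O)C(C)(O)CC(C)CN(C)C(C)C(O)C1(C)O
doxycycline,CC1c2cccc(O)c2C(=O)C2=C(O)C3(O)C(=O)C(C(N)=O)=C(O)C(N(C)C)C3C(O)C21
fluoxetine,CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1
sertraline,CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21
diazepam,CN1c2ccc(Cl)cc2C(=Nc2ccccc2)c2ccccc2C1=O
alprazolam,Cc1nnc2n1-c1ccc(Cl)cc1C(c1ccccc1)=NC2
morphine,CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5
codeine,COc1ccc2CC3C4C=CC(O)C5Oc1c2C45CCN3C
tramadol,CN(C)CC1CCCCC1(O)c1cccc(OC)c1
lidocaine,CCN(CC)CC(=O)Nc1c(C)cccc1C
dexamethasone,CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO
prednisolone,CC12CC(O)C3C(CCC4=CC(=O)C=CC43C)C1CCC2(O)C(=O)CO
salbutamol,CC(C)(C)NCC(O)c1ccc(O)c(CO)c1
montelukast,CC(C)(O)c1ccccc1CCC(SCC1(CC(=O)O)CC1)c1cccc(C=Cc2ccc3ccc(Cl)cc3n2)c1
levothyroxine,NC(Cc1cc(I)c(Oc2cc(I)c(O)c(I)c2)c(I)c1)C(=O)O
furosemide,NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl
hydrochlorothiazide,NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O
captopril,CC(CS)C(=O)N1CCCC1C(=O)O
lisinopril,NCCCCC(NC(CCc1ccccc1)C(=O)O)C(=O)N1CCCC1C(=O)O
losartan,CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1
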