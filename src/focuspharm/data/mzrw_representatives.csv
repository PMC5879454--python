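compound_id,smiles
emodin,Cc1cc(O)c2c(c1)C(=O)c1cc(O)cc(O)c1C2=O
amygdalin,N#CC(OC1OC(COC2OC(CO)C(O)C(O)C2O)C(O)C(O)C1O)c1ccccc1
albiflorin,CC1(O)CC2(COC3OC(CO)C(O)C(O)C3O)C(OC(=O)c3ccccc3)CC1C2(C)C
honokiol,C=CCc1ccc(-c2cc(CC=C)ccc2O)c(O)c1
naringin,CC1OC(OC2C(Oc3cc(O)c4c(c3)OC(c3ccc(O)cc3)CC4=O)OC(CO)C(O)C2O)C(O)C(O)C1O
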