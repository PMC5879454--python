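compound_id,target_id,detail
emodin,ESR2,most-similar-ligand
emodin,ESR1,most-similar-ligand
emodin,SRC,most-similar-ligand
emodin,PIM1,most-similar-ligand
emodin,IGF1R,most-similar-ligand
emodin,PPARG,most-similar-ligand
emodin,CYP1B1,most-similar-ligand
emodin,MET,most-similar-ligand
emodin,AKR1B1,most-similar-ligand
emodin,ALOX5,most-similar-ligand
emodin,FLT3,most-similar-ligand
emodin,CSNK2A1,most-similar-ligand
emodin,AXL,most-similar-ligand
emodin,TNKS2,most-similar-ligand
amygdalin,SLC5A4,most-similar-ligand
amygdalin,ACHE,most-similar-ligand
amygdalin,SLC5A1,most-similar-ligand
amygdalin,P2RY14,most-similar-ligand
amygdalin,SLC5A2,most-similar-ligand
amygdalin,CA14,most-similar-ligand
amygdalin,CA12,most-similar-ligand
amygdalin,CA2,most-similar-ligand
amygdalin,CA9,most-similar-ligand
amygdalin,CA1,most-similar-ligand
albiflorin,SLC5A4,most-similar-ligand
albiflorin,SLC5A1,most-similar-ligand
albiflorin,SLC5A2,most-similar-ligand
albiflorin,CA12,most-similar-ligand
albiflorin,CA2,most-similar-ligand
albiflorin,CA14,most-similar-ligand
albiflorin,CA9,most-similar-ligand
honokiol,CYP19A1,most-similar-ligand
honokiol,ESR2,most-similar-ligand
honokiol,HSD17B2,most-similar-ligand
honokiol,HSD17B1,most-similar-ligand
honokiol,ESR1,most-similar-ligand
honokiol,SLC22A6,most-similar-ligand
honokiol,MIF,most-similar-ligand
naringin,ACHE,most-similar-ligand
naringin,SLC5A4,most-similar-ligand
naringin,AKR1B1,most-similar-ligand
naringin,SLC5A2,most-similar-ligand
naringin,ADORA1,most-similar-ligand
naringin,CA14,most-similar-ligand
naringin,CA12,most-similar-ligand
naringin,SLC5A1,most-similar-ligand
naringin,CA2,most-similar-ligand
naringin,CA9,most-similar-ligand
naringin,CA1,most-similar-ligand
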