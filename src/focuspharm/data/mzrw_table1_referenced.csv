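compound_id,target_id,citation_tag
emodin,ESR1,cit:emodin-ESR1
emodin,ESR2,cit:emodin-ESR2
emodin,CSNK2A1,cit:emodin-CSNK2A1
emodin,EPHX2,cit:emodin-EPHX2
emodin,PTP4A3,cit:emodin-PTP4A3
emodin,LCK,cit:emodin-LCK
emodin,ELANE,cit:emodin-ELANE
honokiol,PTGS1,cit:honokiol-PTGS1
honokiol,PTGS2,cit:honokiol-PTGS2
honokiol,ALOX5,cit:honokiol-ALOX5
honokiol,CNR1,cit:honokiol-CNR1
honokiol,CNR2,cit:honokiol-CNR2
honokiol,GABA_A,cit:honokiol-GABA_A
honokiol,RXR,cit:honokiol-RXR
naringin,CYP19A1,cit:naringin-CYP19A1
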