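target_id,disorder,pathway,note,citation_tag
ACHE,constipation,acetylcholine,linked:amygdalin;naringin,cit:ACHE-GI
ADORA1,constipation,purine,linked:naringin,cit:adenosine-constipation
CNR1,constipation,cannabinoid,linked:honokiol,cit:CNR1-motility
CYP19A1,constipation,estrogen,linked:honokiol;naringin,cit:aromatase-estrogen
ESR2,constipation,estrogen,linked:emodin;honokiol,cit:ESR2-defecation
PTGS1,constipation,prostaglandin,linked:honokiol,cit:PTGS1-STC
PTGS2,constipation,prostaglandin,linked:honokiol,cit:PTGS2-STC
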