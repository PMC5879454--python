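group_label,compound_id
SM2,emodin
SM2,chrysophanol
SM2,physcion
SM2,aloe_emodin
SM2,rhein
SM2,citreorosein
SM2,questin
SM3,amygdalin
SM3,prunasin
SM3,sambunigrin
SM4,albiflorin
SM4,paeoniflorin
SM4,oxypaeoniflorin
SM4,galloylpaeoniflorin
SM4,benzoylpaeoniflorin
SM4,mudanpioside_like
SM5,honokiol
SM5,magnolol
SM5,methylhonokiol
SM5,methylmagnolol
SM5,dihydrohonokiol
SM5,obovatol_like
SM6,naringin
SM6,narirutin
SM6,hesperidin
SM6,neohesperidin
SM6,poncirin
SM6,didymin
SM6,eriocitrin
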