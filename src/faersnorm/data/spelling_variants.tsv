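variant	preferred
sulphasalazine	sulfasalazine
sulphate	sulfate
sulphur	sulfur
sulphadiazine	sulfadiazine
sulphamethoxazole	sulfamethoxazole
frusemide	furosemide
oestrogen	estrogen
oestradiol	estradiol
oestriol	estriol
aluminium	aluminum
anaesthetic	anesthetic
haemoglobin	hemoglobin
adrenaline	epinephrine
noradrenaline	norepinephrine
paracetamol	acetaminophen
salbutamol	albuterol
ciclosporin	cyclosporine
beclometasone	beclomethasone
colecalciferol	cholecalciferol
phenobarbitone	phenobarbital
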