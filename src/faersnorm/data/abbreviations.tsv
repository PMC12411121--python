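abbreviation	expansion
hcl	hydrochloride
hbr	hydrobromide
hctz	hydrochlorothiazide
asa	aspirin
apap	acetaminophen
mtx	methotrexate
vit	vitamin
er	extended release
xr	extended release
sr	sustained release
smx	sulfamethoxazole
tmp	trimethoprim
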