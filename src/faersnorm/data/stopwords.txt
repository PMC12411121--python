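# Tokens ignored by the word-split matching step.
AND
WITH
FOR
THE
NOS
UNK
UNKNOWN
OTC
KIT
PACK
DRUG
PRODUCT
GENERIC
BRAND
PLUS
FORTE
EXTRA
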