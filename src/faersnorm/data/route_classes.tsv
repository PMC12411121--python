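token	route_class
ORAL	ORAL
ORALLY	ORAL
PO	ORAL
BY MOUTH	ORAL
SUBLINGUAL	ORAL
BUCCAL	ORAL
OPHTHALMIC	OPHTHALMIC
INTRAOCULAR	OPHTHALMIC
EYE	OPHTHALMIC
TOPICAL	TOPICAL
TRANSDERMAL	TOPICAL
CUTANEOUS	TOPICAL
SKIN	TOPICAL
INTRAVENOUS	PARENTERAL
INTRAVENOUS DRIP	PARENTERAL
IV	PARENTERAL
INTRAMUSCULAR	PARENTERAL
IM	PARENTERAL
SUBCUTANEOUS	PARENTERAL
SC	PARENTERAL
SUBQ	PARENTERAL
PARENTERAL	PARENTERAL
INJECTION	PARENTERAL
INHALATION	INHALATION
INHALED	INHALATION
RESPIRATORY (INHALATION)	INHALATION
NEBULIZED	INHALATION
RECTAL	RECTAL
NASAL	NASAL
INTRANASAL	NASAL
VAGINAL	VAGINAL
OTIC	OTHER
AURICULAR (OTIC)	OTHER
INTRATHECAL	OTHER
INTRA-ARTICULAR	OTHER
URETHRAL	OTHER
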