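# Tokens removed by the route/dose-form stripping stage of the cleaning
# cascade (one per line, case-insensitive). Routes of administration and
# the dose-form words that commonly trail FAERS drug names.
ORAL
ORALLY
PO
SUBLINGUAL
BUCCAL
TOPICAL
TRANSDERMAL
CUTANEOUS
OPHTHALMIC
OTIC
NASAL
INHALATION
INHALED
RESPIRATORY
RECTAL
VAGINAL
INTRAVENOUS
IV
INTRAMUSCULAR
IM
SUBCUTANEOUS
SC
SUBQ
PARENTERAL
INJECTION
INJECTABLE
INFUSION
TABLET
TABLETS
TAB
TABS
CAPSULE
CAPSULES
CAP
CAPS
CREAM
OINTMENT
GEL
LOTION
PATCH
PATCHES
SOLUTION
SUSPENSION
SYRUP
ELIXIR
DROPS
DROP
SPRAY
SUPPOSITORY
AEROSOL
POWDER
LOZENGE
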