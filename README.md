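# faersnorm

Standardize free-text drug records from FAERS-format files to
ingredient-level drug concepts (RxNorm-style) and ATC codes.

## The problem

Spontaneous adverse-event reporting systems such as the FDA Adverse Event
Reporting System (FAERS) record drug names as free text: misspelled brand
names, dosage and route fragments glued onto ingredient names, national
spelling variants, application numbers instead of names. Pharmacovigilance
analyses need those records standardized — to an ingredient-level drug
concept for signal detection, and to an Anatomical Therapeutic Chemical
(ATC) level-5 code for the drug-utilization studies that key on ATC.

`faersnorm` implements that standardization as a deterministic, fully
auditable pipeline working only from offline vocabulary tables:

1. **Six-step stop-on-first-success cascade** from a drug record to a drug
   concept: (1) the verbatim `drugname` matched through progressively
   cleaned variants (trailing dots → special characters/parentheticals →
   dosages → routes) against preferred terms *and* synonyms; (2) the
   reported active ingredient(s) in `prod_ai`; (3) a brand registry
   (Article-57-style brand → ingredient); (4) the NDA application number
   (Orange-Book-style); (5) word-by-word splitting of the name; (6) a
   user-maintained custom verbatim list. All name lookups use a canonical
   form (lowercase, diacritics folded, word order, abbreviations and
   UK/US spellings unified) — exact matching only, never fuzzy.
2. **Roll-up** of whatever term type matched (brand, clinical drug form,
   …) to one of two final term types: single ingredient or multiple
   ingredients, with an option to expand combinations into their single
   ingredients. Dose-form matches roll up to nothing by design.
3. **ATC resolution with abstention.** An ingredient may hold several ATC
   codes split by route (oral timolol C07AA06 vs. ophthalmic S01ED01) or
   strength (finasteride 1 mg D11AX10 vs. 5 mg G04CB01). The record's
   route, dose amount/unit and dose form narrow the crosswalk candidates;
   exactly one survivor yields a code, anything else is a deliberate
   abstention — a wrong code is worse than no code.

A synthetic-data module generates toy vocabularies and FAERS files with
*planted ground truth*, so the entire pipeline is testable end to end with
no licensed vocabulary download.

## Worked example

```sh
python examples/standardize_corpus.py
```

generates a 1,000-record synthetic corpus and prints:

```
drug records:          1000
unique drug records:   765
mapped to drug concept: 944 (94.4%) records, 715 (93.5%) unique
mapped to ATC code:     750 (75.0%) records, 569 (74.4%) unique
per-step matches (unique records):
  step 1 NAME_MATCH         434
  step 2 ACTIVE_INGREDIENT  95
  step 3 BRAND_REGISTRY     88
  step 4 NDA                46
  step 5 WORD_SPLIT         44
  step 6 CUSTOM             8
```

94.4% of records resolve to an ingredient-level concept; the unmapped
remainder is dominated by planted misspellings, which the exact-match
cascade deliberately does not rescue. ATC coverage is lower than concept
coverage because ATC resolution additionally requires unambiguous
route/strength evidence. `examples/atc_disambiguation.py` and
`examples/cleaning_cascade.py` walk through the ATC abstention rule and
the cleaning cascade on single records.

The same pipeline is available from the shell:

```sh
faersnorm gen --out-dir fx --n-records 500 --seed 7
faersnorm map --input fx/drug.txt --vocab-dir fx/vocab --out-dir out
faersnorm report --mapping-table out/mapping_table.tsv
```

`map` writes a per-unique-record mapping table with the full audit trail
(variants tried, matched step, concepts, ATC outcome, notes) plus coverage
reports in text and JSON.

## Layout

- `src/faersnorm/records.py` — FAERS drug-file parsing, 7-field record identity
- `src/faersnorm/normalize.py` — cleaning cascade, canonical form (lexicons in `data/`)
- `src/faersnorm/vocab.py` — offline vocabulary tables, indexes, lookups
- `src/faersnorm/mapper.py` — the six-step cascade with audit trail
- `src/faersnorm/rollup.py` — roll-up to ingredient level, expansion
- `src/faersnorm/atc.py` — evidence derivation and ATC resolution
- `src/faersnorm/fixtures.py` — synthetic vocabularies/corpora with ground truth
- `src/faersnorm/report.py`, `cli.py` — orchestration, coverage stats, CLI
- `docs/methods.md` — the model, its assumptions, and design choices
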