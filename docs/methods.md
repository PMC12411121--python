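# Methods

## Scope and data model

`faersnorm` standardizes one *drug record* at a time: a row of a
FAERS-format DRUG file with nine fields (a report identifier, a drug
sequence number, and the seven descriptive fields `drugname`, `prod_ai`,
`route`, `dose_amt`, `dose_form`, `dose_unit`, `nda_num`). Empty,
whitespace-only and literal `NULL` cells parse to a distinguished MISSING
value. A *unique drug record* is the 7-tuple of descriptive fields
compared byte-exactly, with MISSING equal only to MISSING; uniqueness is
defined on the fields as reported, not on cleaned values, so trimming or
case differences produce distinct unique records. This choice can
slightly inflate unique-record counts but keeps the definition
assumption-free.

The vocabulary side is a set of delimited offline tables emulating an
OHDSI-style standardized drug vocabulary: concepts (id, name, vocabulary,
term type, standard flag), synonyms, relationships, ingredient strengths,
a brand→ingredient registry (Article-57-like), an NDA→ingredient table
(Orange-Book-like), a custom verbatim mapping list, and an
ingredient→ATC crosswalk. Only fixture-scale tables ship with the
repository; the loaders accept tables of any size with the same columns.

## Name normalization

Two mechanisms, used for different purposes:

**Cleaning cascade** (matching variants, least destructive first):
`RAW` (whitespace trim) → `TRIM` (trailing spaces/dots) →
`SPECIAL_CHARS` (parenthetical/bracket groups dropped; other symbols to
spaces; `.`/`%`/`/` survive so dosage tokens stay intact) → `DOSAGE`
(number+unit tokens such as `500MG`, `0.5%`, `5 mg/ml`; bare digits that
are part of a name, e.g. `B12`, are kept) → `ROUTE` (tokens from a
shipped route/dose-form lexicon). Stages are cumulative, idempotent and
length-non-increasing; empty variants are dropped. The exact dosage
patterns and route lexicon are plain-text data files
(`src/faersnorm/data/`), overridable per `Normalizer` instance, because
no authoritative enumeration of these patterns exists — the shipped set
is this package's documented choice.

**Canonical form** (the lookup key for every name index): lowercase, NFKD
diacritic folding, punctuation to spaces, per-token abbreviation
expansion (`hcl → hydrochloride`) and UK→US spelling unification
(`sulphasalazine → sulfasalazine`) from shipped tables, then
lexicographic token sort. Token sorting makes matching invariant to word
order; the tables are closed under their own mapping at load time so the
function is idempotent. This is an offline stand-in for a live
drug-name normalization service; a custom `Normalizer` can be injected
where different behavior is wanted.

There is deliberately **no fuzzy matching**: the cascade is exact-match
based, and a misspelled name (the classic `cardiazem` for `cardizem`)
is *supposed* to end up unmapped rather than be rescued by edit distance.

## The mapping cascade

Steps run in fixed order; the first step that produces at least one
ingredient-level concept stops the cascade. "Produces" includes roll-up:
a name that matches only a dose-form concept (whose roll-up is empty)
does not stop the cascade. Details per step:

1. Each cascade variant of `drugname` is looked up against preferred
   terms and synonyms; the first variant with ≥1 hit wins, and among
   multiple hits a total tie-break order applies (standard before
   non-standard, standard vocabulary before extension, then
   ingredient > multi-ingredient > brand > other term types, then lowest
   concept id).
2. `prod_ai` may carry several ingredients separated by `\` or `;`
   (FAERS convention): parts are matched independently; two or more
   matched ingredients resolve to the multi-ingredient concept with
   exactly that constituent set when one exists, else to the ingredient
   set; a partially matched list is flagged in the notes and treated as
   mapped to the resolvable part.
3. Brand registry: the same cascade variants are tried against the
   registry (cleaning is generic, so registry matching benefits from it
   too); the registered ingredient *name* is then resolved by
   canonical-form lookup only — registry names are already clean.
4. NDA numbers compare digits-only with leading zeros stripped; the
   registered ingredient name resolves as in step 3.
5. Word split: whitespace tokens of the most-cleaned variant, skipping
   tokens shorter than 3 characters (configurable) and a stopword list;
   per token, multi-ingredient hits take priority over single-ingredient
   hits over brand hits; the union of per-token hits is the match. No
   minimum fraction of matching tokens is required — the union+priority
   rule is this package's documented choice.
6. Custom list: verbatim match only (case-insensitive, trimmed), no
   cleaning variants — the list's purpose is to pin pathological strings
   exactly.

Every record gets a `MappingResult` with the full audit trail: variants
tried, the matched step, raw and rolled-up concepts, the ATC outcome, and
free-text notes. The trail is what makes mapping-correctness review
possible.

## Roll-up

Matched concepts of any term type are converted to single-ingredient or
multiple-ingredients form by walking `HAS_INGREDIENT`,
`HAS_BRANDED_INGREDIENT`, `CONSISTS_OF` and `MAPS_TO` relations,
breadth-first, depth-capped at 3 hops (brands may reach ingredients via
a branded product; the cap guarantees termination alongside explicit
cycle detection, which raises). Dose-form concepts roll up to the empty
set — they name a pharmaceutical form, not a drug. When several single
ingredients result, the multi-ingredient concept with exactly that
constituent set replaces them (lowest concept id on ties). An optional
expansion replaces multi-ingredient results with their ≥2 constituent
single ingredients; expansion after mapping is exactly equivalent to
mapping with expansion enabled (tested as a conservation property).

## ATC resolution

From the record and its mapping, four evidence components are derived:
the ingredient set (expanded if multi), strength (numeric `dose_amt`
plus `dose_unit`, mass units normalized to mg; non-numeric amounts
degrade to "no strength" with a diagnostic), the dose-form concept, and
a route class from a shipped route lexicon (UNKNOWN iff the field is
missing or unrecognized). When route is missing but the dose form is
route-specific ("EYE DROPS"), the dose form may set the route class,
flagged in diagnostics. A most-detailed refinement step looks for a
clinical-drug concept matching ingredients+strength (±1% relative after
mg conversion — vocabularies round units; no authoritative tolerance
exists, so 1% is this package's choice), else a clinical-drug-form
matching ingredients+dose form.

Resolution then filters the crosswalk: candidates are the entries for
the single ingredient, or for the combination concept when the record is
multi-ingredient (no combination entry ⇒ abstain by construction —
"multiple ingredients in unknown combination" can never get a code).
Route narrows to entries with matching or wildcard route; strength
narrows to entries whose range admits the value. **Filters narrow, never
veto:** a filter that would empty the candidate set is ignored and the
event noted. Consequences, by construction: a unique candidate is always
assigned (no ambiguity exists to resolve); adding evidence can move an
abstention to a code but can never flip or retract an assigned code
(subset monotonicity); unspecific terms with many wildcard entries
(calcium-like) always abstain without any special-case list. Exactly one
survivor yields its code; zero or several yield abstention.

## The synthetic-data generator

`fixtures.generate_vocabulary` always plants the structural hard cases —
route-split and strength-split ingredients with their real ATC codes
(timolol C07AA06/S01ED01; finasteride D11AX10 at 0.5–1 mg / G04CB01 at
2–10 mg — the band edges are fixture choices bracketing the marketed 1 mg
and 5 mg products), a three-code unspecific ingredient, combinations
with and without a crosswalk entry, an ingredient absent from the
crosswalk, in-vocabulary and registry-only brands, synonyms, NDA numbers
and custom phrases — plus seeded filler ingredients/brands with
pseudo-names, so collisions are checked against everything planted.

`generate_faers_file` draws a scenario per record (which step must
match, or an unmappable misspelling) and decorates names with reversible
surface noise (case, single-token dosage suffix, route suffix,
parenthetical, trailing punctuation) that the cleaning cascade inverts
by design. Misspellings are single-character transpositions *verified*
absent from every index. Expected outcomes — step, final concepts, ATC
code or abstention — are derived analytically from the ledger of planted
names and the crosswalk filter rule, in generator-side code independent
of the pipeline, and written to a separate ground-truth file.

Default rates (e.g. 5% misspellings, 10% ingredient-only records, 30%
case noise, 35% missing evidence fields) are chosen to exercise every
step with material frequency while keeping the corpus majority-clean,
roughly matching the situation in public spontaneous-reporting data
where most records do map. They are defaults of the study conditions,
not tuning knobs. What passing the generator-as-oracle test shows is
that the pipeline implements the documented rules exactly on data whose
pathologies come from this taxonomy; it does not certify coverage or
accuracy on real FAERS text, whose error distribution is unknown and
whose vocabularies are orders of magnitude larger.

## Problem sizes and numerical choices

The test suite runs corpora of 400–5,000 records over seeded generators
(fixed seeds; hypothesis for parser/normalizer properties) and checks
canonical-form idempotence and permutation invariance on 10,000 random
strings; the acceptance script uses a 2,000-record corpus. These sizes
keep full runs in seconds while exercising every scenario hundreds of
times. Determinism everywhere: `random.Random(seed)` is the only
randomness source; index construction is order-independent; all
tie-breaks are total orders ending in lowest concept id.

## Known limitations

- Exact matching only; misspellings and truncations stay unmapped.
- The shipped cleaning patterns, abbreviation and spelling tables are
  small curated sets, not exhaustive references; they are data files
  precisely so users can extend them.
- The ATC crosswalk format is defined here at ingredient granularity
  with route/strength constraints; real crosswalks with richer
  conditions (indication, salt form) would need extra columns.
- Record identity is byte-exact; upstream case-report deduplication and
  outcome coding are out of scope.
- Multi-ingredient strength matching is not attempted (a single
  `dose_amt` cannot be attributed to one constituent).
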