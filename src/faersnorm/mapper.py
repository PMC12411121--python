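"""The six-step stop-on-first-success mapping cascade.

Each FAERS drug record is pushed through a fixed sequence of lookups, and
the first step that yields at least one ingredient-level concept wins:

1. the verbatim drug name, tried through progressively cleaned variants,
   against vocabulary preferred terms and synonyms;
2. the reported active ingredient(s) (``prod_ai``), same matching;
3. the drug name against the brand registry, then the registered
   ingredient name against the vocabulary;
4. the NDA application number against the NDA table, then the registered
   ingredient name against the vocabulary;
5. word-by-word splitting of the drug name, each token matched with
   multi-ingredient, single-ingredient or brand-name concepts;
6. a user-maintained custom list of verbatim name -> concept mappings.

"Yields an ingredient-level concept" means the match survives roll-up:
a name that only matches a dose-form concept does not stop the cascade.
A full audit trail (variants tried, step matched, notes) is recorded for
every record so mapping decisions can be reviewed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .records import MISSING, DrugRecord, RecordKey, record_key
from .rollup import _multi_for_ingredient_set, finalize
from .vocab import Concept, TermType, VocabIndex, best_concept

UNMAPPED = "UNMAPPED"

STEP_NAME_MATCH = 1
STEP_ACTIVE_INGREDIENT = 2
STEP_BRAND_REGISTRY = 3
STEP_NDA = 4
STEP_WORD_SPLIT = 5
STEP_CUSTOM = 6
ALL_STEPS = frozenset(range(1, 7))

STEP_LABELS = {
    STEP_NAME_MATCH: "NAME_MATCH",
    STEP_ACTIVE_INGREDIENT: "ACTIVE_INGREDIENT",
    STEP_BRAND_REGISTRY: "BRAND_REGISTRY",
    STEP_NDA: "NDA",
    STEP_WORD_SPLIT: "WORD_SPLIT",
    STEP_CUSTOM: "CUSTOM",
}

# FAERS prod_ai lists multiple ingredients separated by backslash or semicolon
_PROD_AI_SEP = re.compile(r"[\\;]")


@dataclass
class MapOptions:
    """Cascade configuration.

    enabled_steps
        Which of steps 1-6 run; disabling a step can only lower coverage.
    use_synonyms
        Match vocabulary synonyms in addition to preferred terms.
    expand_ingredients
        Replace a final multi-ingredient concept by its single ingredients.
    min_token_len / extra stopwords come from the normalizer's lexicons.
    """

    enabled_steps: frozenset[int] = ALL_STEPS
    use_synonyms: bool = True
    expand_ingredients: bool = False
    min_token_len: int = 3


@dataclass
class MappingResult:
    """Audit of one record's journey through the cascade."""

    key: RecordKey
    matched_step: int | None = None  # 1..6, or None == UNMAPPED
    variant_used: str | None = None
    raw_concepts: frozenset[Concept] = frozenset()
    final_concepts: frozenset[Concept] = frozenset()
    atc_code: str | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def mapped(self) -> bool:
        return self.matched_step is not None

    @property
    def step_label(self) -> str:
        if self.matched_step is None:
            return UNMAPPED
        return STEP_LABELS[self.matched_step]


def word_split_match(
    name: str, index: VocabIndex, options: MapOptions | None = None
) -> set[Concept]:
    """Split ``name`` on whitespace and match each token against
    multi-ingredient, single-ingredient and brand-name concepts, in that
    priority per token; returns the union of per-token hits.

    Tokens shorter than ``min_token_len`` and stopword tokens are skipped.
    """
    options = options or MapOptions()
    stopwords = index.normalizer.stopwords
    hits: set[Concept] = set()
    for token in name.split():
        if len(token) < options.min_token_len or token.lower() in stopwords:
            continue
        concepts = index.lookup_exact(token, include_synonyms=options.use_synonyms)
        for tt in (TermType.MULTI_INGREDIENT, TermType.INGREDIENT, TermType.BRAND_NAME):
            typed = {c for c in concepts if c.term_type is tt}
            if typed:
                hits |= typed
                break
    return hits


def custom_lookup(index: VocabIndex, name: str) -> Concept | None:
    """Verbatim custom-list lookup (case-insensitive, trimmed); the cleaning
    cascade deliberately does not apply here."""
    return index.custom_lookup(name)


def _finalize_multi(
    raw: set[Concept], index: VocabIndex, options: MapOptions, notes: list[str]
) -> frozenset[Concept]:
    """Roll up; when several single ingredients result, prefer the matching
    multi-ingredient concept if the vocabulary has one (unless expansion is
    requested)."""
    final = finalize(raw, index, expand=options.expand_ingredients)
    if not options.expand_ingredients:
        ingredients = {c for c in final if c.term_type is TermType.INGREDIENT}
        if len(ingredients) >= 2 and ingredients == final:
            multi = _multi_for_ingredient_set(index, ingredients)
            if multi is not None:
                notes.append(
                    f"resolved {len(ingredients)} ingredients to "
                    f"multi-ingredient concept {multi.concept_id}"
                )
                return frozenset({multi})
    return frozenset(final)


def _try_concepts(
    raw: set[Concept],
    index: VocabIndex,
    options: MapOptions,
    notes: list[str],
) -> frozenset[Concept] | None:
    """Roll up candidate matches; None when nothing survives roll-up."""
    if not raw:
        return None
    final = _finalize_multi(raw, index, options, notes)
    return final if final else None


def map_record(
    record: DrugRecord, index: VocabIndex, options: MapOptions | None = None
) -> MappingResult:
    """Run the cascade for one record; always returns a result (UNMAPPED
    when every step fails)."""
    options = options or MapOptions()
    result = MappingResult(key=record_key(record))
    notes = result.notes
    normalizer = index.normalizer

    def succeed(step: int, raw: set[Concept], final: frozenset[Concept],
                variant: str | None) -> MappingResult:
        result.matched_step = step
        result.variant_used = variant
        result.raw_concepts = frozenset(raw)
        result.final_concepts = final
        notes.append(f"matched at step {step} ({STEP_LABELS[step]})")
        return result

    cascade = (
        normalizer.clean_cascade(record.drugname)
        if record.drugname is not MISSING
        else []
    )

    # step 1 — drug name vs preferred terms and synonyms, iterating variants
    if STEP_NAME_MATCH in options.enabled_steps:
        for stage, variant in cascade:
            hits = index.lookup_exact(variant, include_synonyms=options.use_synonyms)
            notes.append(f"step 1: variant [{stage}] {variant!r}: {len(hits)} hit(s)")
            if hits:
                chosen = best_concept(hits)
                final = _try_concepts({chosen}, index, options, notes)
                if final is not None:
                    return succeed(STEP_NAME_MATCH, {chosen}, final, variant)
                notes.append(
                    f"step 1: concept {chosen.concept_id} rolled up to "
                    "nothing (dose form); continuing"
                )

    # step 2 — reported active ingredient(s)
    if STEP_ACTIVE_INGREDIENT in options.enabled_steps and record.prod_ai is not MISSING:
        parts = [p.strip() for p in _PROD_AI_SEP.split(record.prod_ai) if p.strip()]
        matched: set[Concept] = set()
        unmatched: list[str] = []
        for part in parts:
            part_hit: Concept | None = None
            for stage, variant in normalizer.clean_cascade(part):
                hits = index.lookup_exact(variant, include_synonyms=options.use_synonyms)
                if hits:
                    part_hit = best_concept(hits)
                    break
            if part_hit is not None:
                matched.add(part_hit)
            else:
                unmatched.append(part)
        notes.append(
            f"step 2: prod_ai {len(parts)} part(s), {len(matched)} matched"
        )
        if matched:
            if unmatched:
                notes.append(
                    "step 2: partial match, unmatched ingredient(s): "
                    + "; ".join(unmatched)
                )
            final = _try_concepts(matched, index, options, notes)
            if final is not None:
                return succeed(STEP_ACTIVE_INGREDIENT, matched, final, record.prod_ai)

    # step 3 — brand registry on cleaned drug-name variants
    if STEP_BRAND_REGISTRY in options.enabled_steps:
        for stage, variant in cascade:
            ingredient_name = index.brand_to_ingredient(variant)
            if ingredient_name is None:
                continue
            notes.append(
                f"step 3: registry brand [{stage}] {variant!r} -> "
                f"{ingredient_name!r}"
            )
            hits = index.lookup_exact(
                ingredient_name, include_synonyms=options.use_synonyms
            )
            if hits:
                chosen = best_concept(hits)
                final = _try_concepts({chosen}, index, options, notes)
                if final is not None:
                    return succeed(STEP_BRAND_REGISTRY, {chosen}, final, variant)
            notes.append(
                f"step 3: registry ingredient {ingredient_name!r} not in vocabulary"
            )

    # step 4 — NDA number -> registered ingredient
    if STEP_NDA in options.enabled_steps and record.nda_num is not MISSING:
        ingredient_name = index.nda_lookup(record.nda_num)
        if ingredient_name is not None:
            notes.append(f"step 4: NDA {record.nda_num!r} -> {ingredient_name!r}")
            hits = index.lookup_exact(
                ingredient_name, include_synonyms=options.use_synonyms
            )
            if hits:
                chosen = best_concept(hits)
                final = _try_concepts({chosen}, index, options, notes)
                if final is not None:
                    return succeed(STEP_NDA, {chosen}, final, record.nda_num)

    # step 5 — word splitting of the most-cleaned variant
    if STEP_WORD_SPLIT in options.enabled_steps and cascade:
        cleaned = cascade[-1][1]
        hits = word_split_match(cleaned, index, options)
        notes.append(f"step 5: word split of {cleaned!r}: {len(hits)} hit(s)")
        if hits:
            final = _try_concepts(set(hits), index, options, notes)
            if final is not None:
                return succeed(STEP_WORD_SPLIT, set(hits), final, cleaned)

    # step 6 — custom verbatim list
    if STEP_CUSTOM in options.enabled_steps and record.drugname is not MISSING:
        concept = custom_lookup(index, record.drugname)
        if concept is not None:
            notes.append(f"step 6: custom mapping -> concept {concept.concept_id}")
            final = _try_concepts({concept}, index, options, notes)
            if final is not None:
                return succeed(STEP_CUSTOM, {concept}, final, record.drugname.strip())

    notes.append("unmapped: all steps exhausted")
    return result


def map_records(
    records,
    index: VocabIndex,
    options: MapOptions | None = None,
) -> dict[RecordKey, MappingResult]:
    """Map each unique record key once; returns key -> MappingResult."""
    options = options or MapOptions()
    results: dict[RecordKey, MappingResult] = {}
    for record in records:
        key = record_key(record)
        if key not in results:
            results[key] = map_record(record, index, options)
    return results
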