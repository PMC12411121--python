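"""ATC code resolution from a mapped record's evidence.

One active ingredient can hold several ATC level-5 codes, split by
therapeutic use — typically route of administration (oral timolol is a
beta blocker, C07AA06; timolol eye drops treat glaucoma, S01ED01) or
strength (low-dose finasteride for androgenetic alopecia, D11AX10;
high-dose for benign prostatic hyperplasia, G04CB01). A record therefore
supplies four pieces of evidence — ingredients, strength, dose form and
brand — and a crosswalk entry survives only while the evidence is
consistent with it. Exactly one surviving entry yields a code; zero or
several yield an abstention: a wrong code is worse than no code.

Evidence is treated as a narrowing device, never a veto: a filter that
would eliminate *every* candidate is ignored (and flagged in the
diagnostics), so a unique candidate is always assigned and adding
evidence can resolve an ambiguity but never flip an assigned code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from .mapper import MappingResult
from .records import MISSING, DrugRecord
from .rollup import _multi_for_ingredient_set, expand_ingredients
from .vocab import (
    AtcCrosswalkEntry,
    Concept,
    RelKind,
    RouteClass,
    TermType,
    VocabIndex,
    to_mg,
)

_NUMERIC_RE = re.compile(r"^\s*\d+(?:[.,]\d+)?\s*$")

#: relative tolerance for strength comparison after mg conversion,
#: accommodating unit rounding in vocabularies
STRENGTH_RTOL = 0.01


def _load_route_map() -> dict[str, RouteClass]:
    text = (resources.files("faersnorm.data") / "route_classes.tsv").read_text(
        encoding="utf-8"
    )
    out: dict[str, RouteClass] = {}
    for line in text.splitlines()[1:]:
        line = line.strip()
        if not line:
            continue
        token, _, cls = line.partition("\t")
        out[token.strip().upper()] = RouteClass(cls.strip())
    return out


_ROUTE_MAP: dict[str, RouteClass] | None = None


def route_map() -> dict[str, RouteClass]:
    global _ROUTE_MAP
    if _ROUTE_MAP is None:
        _ROUTE_MAP = _load_route_map()
    return _ROUTE_MAP


def classify_route(route: str | None) -> RouteClass:
    """Map a free-text route field to a route class; UNKNOWN when the field
    is missing or unrecognized."""
    if route is MISSING or route is None:
        return RouteClass.UNKNOWN
    text = route.strip().upper()
    if not text:
        return RouteClass.UNKNOWN
    mapping = route_map()
    if text in mapping:
        return mapping[text]
    for token in re.split(r"[^A-Z]+", text):
        if token in mapping:
            return mapping[token]
    return RouteClass.UNKNOWN


@dataclass(frozen=True)
class DrugComponents:
    """Evidence derived from a record plus its concept mapping."""

    ingredients: frozenset[Concept]
    multi_concept: Concept | None = None
    strength: tuple[float, str] | None = None  # (amount, unit), mg-normalized
    dose_form: Concept | None = None
    brand: Concept | None = None
    route_class: RouteClass = RouteClass.UNKNOWN
    diagnostics: tuple[str, ...] = ()


def _parse_strength(
    dose_amt: str | None, dose_unit: str | None, diagnostics: list[str]
) -> tuple[float, str] | None:
    if dose_amt is MISSING or dose_amt is None:
        return None
    if not _NUMERIC_RE.match(dose_amt):
        diagnostics.append(f"dose_amt {dose_amt!r} is not numeric; strength ignored")
        return None
    amount = float(dose_amt.replace(",", ".").strip())
    unit = (dose_unit or "mg").strip().lower()
    amount, unit = to_mg(amount, unit)
    return amount, unit


def derive_components(
    record: DrugRecord, mapping: MappingResult, index: VocabIndex
) -> DrugComponents:
    """Derive ingredient/strength/dose-form/brand/route evidence.

    Unparseable evidence degrades to None/UNKNOWN with a diagnostic; only
    calling this on an UNMAPPED mapping is a contract violation.
    """
    if not mapping.mapped:
        raise ValueError("derive_components called on an UNMAPPED mapping")
    diagnostics: list[str] = []

    ingredients: set[Concept] = set()
    multi: Concept | None = None
    for concept in mapping.final_concepts:
        if concept.term_type is TermType.INGREDIENT:
            ingredients.add(concept)
        elif concept.term_type is TermType.MULTI_INGREDIENT:
            multi = concept if multi is None or concept.concept_id < multi.concept_id else multi
            ingredients |= expand_ingredients(concept, index)
    if multi is None and len(ingredients) >= 2:
        multi = _multi_for_ingredient_set(index, ingredients)

    brand = next(
        (c for c in sorted(mapping.raw_concepts, key=lambda c: c.concept_id)
         if c.term_type is TermType.BRAND_NAME),
        None,
    )

    strength = _parse_strength(record.dose_amt, record.dose_unit, diagnostics)

    dose_form = None
    if record.dose_form is not MISSING:
        hits = {
            c for c in index.lookup_exact(record.dose_form)
            if c.term_type is TermType.DOSE_FORM
        }
        if hits:
            dose_form = min(hits, key=lambda c: c.concept_id)

    route_class = classify_route(record.route)
    if route_class is RouteClass.UNKNOWN and record.dose_form is not MISSING:
        # a route-specific dose form ("EYE DROPS") may stand in for a
        # missing route field
        hinted = classify_route(record.dose_form)
        if hinted is not RouteClass.UNKNOWN:
            route_class = hinted
            diagnostics.append(
                f"route class {hinted.value} inferred from dose form "
                f"{record.dose_form!r}"
            )

    return DrugComponents(
        ingredients=frozenset(ingredients),
        multi_concept=multi,
        strength=strength,
        dose_form=dose_form,
        brand=brand,
        route_class=route_class,
        diagnostics=tuple(diagnostics),
    )


def _strength_close(a: float, b: float) -> bool:
    return abs(a - b) <= STRENGTH_RTOL * max(abs(a), abs(b))


def refine_to_clinical_drug(
    components: DrugComponents, index: VocabIndex
) -> Concept | None:
    """The most detailed drug-level concept the evidence supports: a
    CLINICAL_DRUG matching ingredients + strength, else a
    CLINICAL_DRUG_FORM matching ingredients + dose form, else None."""
    want = {c.concept_id for c in components.ingredients}
    if not want:
        return None

    if components.strength is not None and len(want) == 1:
        amount, unit = components.strength
        candidates = []
        for drug in index.concepts_of_type(TermType.CLINICAL_DRUG):
            entries = index.drug_strengths(drug.concept_id)
            if {e.ingredient_concept_id for e in entries} != want:
                continue
            entry = entries[0]
            e_amount, e_unit = to_mg(entry.amount, entry.unit)
            if e_unit == unit and _strength_close(e_amount, amount):
                candidates.append(drug)
        if candidates:
            return min(candidates, key=lambda c: c.concept_id)

    if components.dose_form is not None:
        candidates = []
        for form in index.concepts_of_type(TermType.CLINICAL_DRUG_FORM):
            parts = {
                e.target_id
                for e in index.out_edges(form.concept_id, (RelKind.HAS_INGREDIENT,))
            }
            forms = {
                e.target_id
                for e in index.out_edges(form.concept_id, (RelKind.HAS_DOSE_FORM,))
            }
            if parts == want and components.dose_form.concept_id in forms:
                candidates.append(form)
        if candidates:
            return min(candidates, key=lambda c: c.concept_id)
    return None


def _entry_allows_strength(
    entry: AtcCrosswalkEntry, strength: tuple[float, str]
) -> bool:
    if entry.strength_min is None and entry.strength_max is None:
        return True
    amount, unit = strength
    entry_unit = (entry.strength_unit or "mg").strip().lower()
    lo = entry.strength_min
    hi = entry.strength_max
    if lo is not None:
        lo, lo_unit = to_mg(lo, entry_unit)
        if lo_unit != unit:
            return True  # incomparable units: cannot contradict the entry
    if hi is not None:
        hi, hi_unit = to_mg(hi, entry_unit)
        if hi_unit != unit:
            return True
    if lo is not None and amount < lo * (1 - STRENGTH_RTOL):
        return False
    if hi is not None and amount > hi * (1 + STRENGTH_RTOL):
        return False
    return True


def resolve_atc(
    components: DrugComponents,
    refined: Concept | None,
    crosswalk: VocabIndex | Iterable[AtcCrosswalkEntry],
    index: VocabIndex | None = None,
) -> str | None:
    """Resolve exactly one ATC code from the crosswalk, or abstain.

    Candidates are the crosswalk entries for the record's ingredient (a
    combination entry for multi-ingredient records). Route and strength
    evidence narrow the candidates; a filter that would empty the set is
    ignored. Exactly one survivor -> its code; zero or several -> None.
    """
    if isinstance(crosswalk, VocabIndex):
        index = index or crosswalk
        all_entries = crosswalk.crosswalk
    else:
        all_entries = list(crosswalk)

    if components.multi_concept is not None or len(components.ingredients) > 1:
        # multi-ingredient: only an explicit combination entry can resolve
        if components.multi_concept is None:
            return None
        lookup_id = components.multi_concept.concept_id
    elif len(components.ingredients) == 1:
        lookup_id = next(iter(components.ingredients)).concept_id
    else:
        return None

    candidates = [e for e in all_entries if e.ingredient_concept_id == lookup_id]
    if not candidates:
        return None

    route = components.route_class
    if route is not RouteClass.UNKNOWN:
        narrowed = [
            e for e in candidates
            if e.route_class in (RouteClass.ANY, route)
        ]
        if narrowed:
            candidates = narrowed

    strength = components.strength
    if strength is None and refined is not None and index is not None:
        if refined.term_type is TermType.CLINICAL_DRUG:
            entries = index.drug_strengths(refined.concept_id)
            if len(entries) == 1:
                strength = to_mg(entries[0].amount, entries[0].unit)
    if strength is not None:
        narrowed = [e for e in candidates if _entry_allows_strength(e, strength)]
        if narrowed:
            candidates = narrowed

    if len(candidates) == 1:
        return candidates[0].atc_code
    return None


def assign_atc(
    record: DrugRecord, mapping: MappingResult, index: VocabIndex
) -> MappingResult:
    """Derive components, refine, resolve, and store the outcome (code or
    abstention) on the mapping result in place."""
    if not mapping.mapped:
        return mapping
    components = derive_components(record, mapping, index)
    refined = refine_to_clinical_drug(components, index)
    code = resolve_atc(components, refined, index)
    mapping.atc_code = code
    mapping.notes.extend(components.diagnostics)
    if refined is not None:
        mapping.notes.append(
            f"refined to {refined.term_type.value} concept {refined.concept_id}"
        )
    mapping.notes.append(
        f"ATC: {code}" if code else "ATC: abstained (no unique candidate)"
    )
    return mapping
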