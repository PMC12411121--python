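"""Roll-up of matched drug concepts to the ingredient level.

A name match can land on any term type — a brand, a clinical drug form, a
dose form. Downstream analysis wants exactly two final term types: single
ingredient or multiple ingredients. Roll-up walks the relationship graph
to get there, with two guard rails:

* a DOSE_FORM concept rolls up to nothing — it names a pharmaceutical
  form, not a drug, and mapping it to a drug would be wrong;
* brand names must terminate at ingredients, never at clinical drug
  forms, even when the brand->ingredient link is indirect (via a branded
  product). Traversal is depth-capped at 3 hops.
"""

from __future__ import annotations

from typing import Iterable

from .vocab import Concept, RelKind, TermType, VocabIndex

_FINAL_TYPES = (TermType.INGREDIENT, TermType.MULTI_INGREDIENT)
_INGREDIENT_RELS = (
    RelKind.HAS_INGREDIENT,
    RelKind.HAS_BRANDED_INGREDIENT,
    RelKind.CONSISTS_OF,
    RelKind.MAPS_TO,
)
_MAX_DEPTH = 3


class RollupCycleError(ValueError):
    """The relationship graph contains a cycle on the roll-up path."""


def _collect_ingredients(
    index: VocabIndex, start: Concept
) -> tuple[set[Concept], set[Concept]]:
    """BFS over ingredient-bearing relations; returns (ingredients,
    multi-ingredient concepts) reachable within the depth cap."""
    ingredients: set[Concept] = set()
    multis: set[Concept] = set()
    frontier = [(start.concept_id, (start.concept_id,))]
    seen = {start.concept_id}
    depth = 0
    while frontier and depth < _MAX_DEPTH:
        depth += 1
        next_frontier: list[tuple[int, tuple[int, ...]]] = []
        for cid, path in frontier:
            for edge in index.out_edges(cid, _INGREDIENT_RELS):
                if edge.target_id in path:
                    cycle = " -> ".join(str(p) for p in (*path, edge.target_id))
                    raise RollupCycleError(f"relationship cycle: {cycle}")
                target = index.concepts[edge.target_id]
                if target.term_type is TermType.INGREDIENT:
                    ingredients.add(target)
                elif target.term_type is TermType.MULTI_INGREDIENT:
                    multis.add(target)
                elif edge.target_id not in seen:
                    seen.add(edge.target_id)
                    next_frontier.append((edge.target_id, (*path, edge.target_id)))
        frontier = next_frontier
    return ingredients, multis


def _multi_for_ingredient_set(
    index: VocabIndex, ingredients: set[Concept]
) -> Concept | None:
    """The MULTI_INGREDIENT concept whose constituent set equals
    ``ingredients``, if one exists (lowest concept_id on ties)."""
    want = {c.concept_id for c in ingredients}
    candidates = []
    for multi in index.concepts_of_type(TermType.MULTI_INGREDIENT):
        parts = {
            e.target_id
            for e in index.out_edges(multi.concept_id, _INGREDIENT_RELS)
            if index.concepts[e.target_id].term_type is TermType.INGREDIENT
        }
        if parts == want:
            candidates.append(multi)
    if not candidates:
        return None
    return min(candidates, key=lambda c: c.concept_id)


def rollup(concept: Concept, index: VocabIndex) -> set[Concept]:
    """Convert a matched concept to its final ingredient-level form.

    Returns a set of concepts whose term types are all INGREDIENT or
    MULTI_INGREDIENT; empty for DOSE_FORM inputs. Idempotent: final-type
    concepts are fixed points.
    """
    if concept.term_type in _FINAL_TYPES:
        return {concept}
    if concept.term_type is TermType.DOSE_FORM:
        return set()

    ingredients, multis = _collect_ingredients(index, concept)
    if multis and not ingredients:
        return multis
    if len(ingredients) == 1 and not multis:
        return ingredients
    if len(ingredients) >= 2:
        multi = _multi_for_ingredient_set(index, ingredients)
        if multi is not None:
            return {multi}
        return ingredients
    return ingredients | multis


def expand_ingredients(concept: Concept, index: VocabIndex) -> set[Concept]:
    """Replace a MULTI_INGREDIENT concept by its constituent single
    ingredients; single ingredients pass through unchanged."""
    if concept.term_type is TermType.INGREDIENT:
        return {concept}
    if concept.term_type is not TermType.MULTI_INGREDIENT:
        raise ValueError(
            f"expand_ingredients expects an ingredient-level concept, got "
            f"{concept.term_type.value} ({concept.concept_id})"
        )
    parts = {
        index.concepts[e.target_id]
        for e in index.out_edges(concept.concept_id, _INGREDIENT_RELS)
        if index.concepts[e.target_id].term_type is TermType.INGREDIENT
    }
    if len(parts) < 2:
        raise ValueError(
            f"MULTI_INGREDIENT concept {concept.concept_id} has "
            f"{len(parts)} ingredient relation(s); expected >= 2"
        )
    return parts


def finalize(
    raw_concepts: Iterable[Concept],
    index: VocabIndex,
    expand: bool = False,
) -> set[Concept]:
    """Roll up a set of matched concepts; optionally expand multi-ingredient
    results into their single ingredients."""
    final: set[Concept] = set()
    for concept in raw_concepts:
        final |= rollup(concept, index)
    if expand:
        expanded: set[Concept] = set()
        for concept in final:
            expanded |= expand_ingredients(concept, index)
        return expanded
    return final
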