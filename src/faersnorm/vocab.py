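"""Offline vocabulary resources: concepts, synonyms, relationships,
strengths, the brand registry, NDA list, custom mappings and the
ingredient->ATC crosswalk.

The tables emulate the layout of an OHDSI-style standardized drug
vocabulary at whatever scale the user supplies; only fixture-scale tables
are bundled with the test suite. All name lookups key on the normalizer's
canonical form, so preferred-term and synonym matching is case-,
word-order- and diacritic-insensitive while FAERS values stay verbatim.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .normalize import Normalizer, default_normalizer


class Vocabulary(str, enum.Enum):
    STANDARD_DRUG = "STANDARD_DRUG"
    DRUG_EXTENSION = "DRUG_EXTENSION"
    ATC = "ATC"


class TermType(str, enum.Enum):
    INGREDIENT = "INGREDIENT"
    MULTI_INGREDIENT = "MULTI_INGREDIENT"
    BRAND_NAME = "BRAND_NAME"
    CLINICAL_DRUG_FORM = "CLINICAL_DRUG_FORM"
    CLINICAL_DRUG = "CLINICAL_DRUG"
    DOSE_FORM = "DOSE_FORM"


class RelKind(str, enum.Enum):
    HAS_INGREDIENT = "HAS_INGREDIENT"
    HAS_BRANDED_INGREDIENT = "HAS_BRANDED_INGREDIENT"
    HAS_DOSE_FORM = "HAS_DOSE_FORM"
    MAPS_TO = "MAPS_TO"
    CONSISTS_OF = "CONSISTS_OF"


class RouteClass(str, enum.Enum):
    ORAL = "ORAL"
    OPHTHALMIC = "OPHTHALMIC"
    TOPICAL = "TOPICAL"
    PARENTERAL = "PARENTERAL"
    INHALATION = "INHALATION"
    RECTAL = "RECTAL"
    NASAL = "NASAL"
    VAGINAL = "VAGINAL"
    OTHER = "OTHER"
    UNKNOWN = "UNKNOWN"
    ANY = "ANY"  # crosswalk wildcard only, never derived from a record


ATC_CODE_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

# term-type preference for tie-breaking ambiguous name matches
_TT_RANK = {
    TermType.INGREDIENT: 0,
    TermType.MULTI_INGREDIENT: 1,
    TermType.BRAND_NAME: 2,
    TermType.CLINICAL_DRUG_FORM: 3,
    TermType.CLINICAL_DRUG: 4,
    TermType.DOSE_FORM: 5,
}


@dataclass(frozen=True, slots=True)
class Concept:
    concept_id: int
    name: str
    vocabulary: Vocabulary
    term_type: TermType
    standard: bool


@dataclass(frozen=True, slots=True)
class Relationship:
    source_id: int
    target_id: int
    kind: RelKind


@dataclass(frozen=True, slots=True)
class StrengthEntry:
    drug_concept_id: int
    ingredient_concept_id: int
    amount: float
    unit: str


@dataclass(frozen=True, slots=True)
class AtcCrosswalkEntry:
    """One ingredient->ATC rule: the code applies when the record's route
    class matches (or the entry says ANY) and its strength, if the entry
    constrains strength, falls inside [strength_min, strength_max]."""

    ingredient_concept_id: int
    atc_code: str
    route_class: RouteClass = RouteClass.ANY
    strength_min: float | None = None
    strength_max: float | None = None
    strength_unit: str | None = None


class VocabLoadError(ValueError):
    """Referential-integrity or schema failure while loading vocabulary."""


#: mass units convertible to mg
MASS_TO_MG = {"mg": 1.0, "g": 1000.0, "mcg": 0.001, "ug": 0.001, "kg": 1e6}


def to_mg(amount: float, unit: str) -> tuple[float, str]:
    """Normalize mass-dimensional strengths to mg; other units pass through."""
    u = unit.strip().lower()
    if u in MASS_TO_MG:
        return amount * MASS_TO_MG[u], "mg"
    return amount, u


def normalize_nda(nda_num: str) -> str:
    """Application numbers compare digits-only, without leading zeros."""
    digits = re.sub(r"\D", "", nda_num)
    return digits.lstrip("0")


class VocabIndex:
    """Read-only lookup structure over the loaded vocabulary tables.

    Construction is deterministic and order-independent: lookups return
    sets, and tie-breaking (:func:`best_concept`) is a total order.
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        synonyms: Iterable[tuple[int, str]] = (),
        relationships: Iterable[Relationship] = (),
        strengths: Iterable[StrengthEntry] = (),
        brand_registry: Mapping[str, str] | Iterable[tuple[str, str]] = (),
        nda_table: Mapping[str, str] | Iterable[tuple[str, str]] = (),
        custom_mappings: Mapping[str, int] | Iterable[tuple[str, int]] = (),
        crosswalk: Iterable[AtcCrosswalkEntry] = (),
        normalizer: Normalizer | None = None,
    ) -> None:
        self.normalizer = normalizer or default_normalizer()
        canon = self.normalizer.canonical_form

        self.concepts: dict[int, Concept] = {}
        for c in concepts:
            if c.concept_id in self.concepts:
                raise VocabLoadError(f"duplicate concept_id {c.concept_id}")
            if c.vocabulary is Vocabulary.ATC and not ATC_CODE_RE.match(c.name):
                raise VocabLoadError(
                    f"concept {c.concept_id}: ATC name {c.name!r} is not a "
                    "level-5 ATC code"
                )
            self.concepts[c.concept_id] = c

        # preferred-term and synonym indexes (kept separate so synonym
        # matching can be switched off)
        self._preferred: dict[str, set[int]] = {}
        self._synonym: dict[str, set[int]] = {}
        for c in self.concepts.values():
            self._preferred.setdefault(canon(c.name), set()).add(c.concept_id)
        for row_no, (cid, text) in enumerate(synonyms, start=1):
            if cid not in self.concepts:
                raise VocabLoadError(
                    f"synonym row {row_no}: concept_id {cid} not loaded"
                )
            self._synonym.setdefault(canon(text), set()).add(cid)

        self.relationships: list[Relationship] = []
        self._out_edges: dict[int, list[Relationship]] = {}
        for row_no, rel in enumerate(relationships, start=1):
            for endpoint in (rel.source_id, rel.target_id):
                if endpoint not in self.concepts:
                    raise VocabLoadError(
                        f"relationship row {row_no}: concept_id {endpoint} "
                        "not loaded"
                    )
            self.relationships.append(rel)
            self._out_edges.setdefault(rel.source_id, []).append(rel)

        self.strengths: list[StrengthEntry] = []
        self._strength_by_drug: dict[int, list[StrengthEntry]] = {}
        for row_no, s in enumerate(strengths, start=1):
            for endpoint in (s.drug_concept_id, s.ingredient_concept_id):
                if endpoint not in self.concepts:
                    raise VocabLoadError(
                        f"strength row {row_no}: concept_id {endpoint} not loaded"
                    )
            if not s.amount > 0:
                raise VocabLoadError(f"strength row {row_no}: amount must be > 0")
            self.strengths.append(s)
            self._strength_by_drug.setdefault(s.drug_concept_id, []).append(s)

        items = brand_registry.items() if hasattr(brand_registry, "items") else brand_registry
        self._brands: dict[str, str] = {}
        for brand, ingredient in items:
            if not ingredient:
                raise VocabLoadError(f"brand {brand!r}: empty ingredient name")
            self._brands[canon(brand)] = ingredient

        items = nda_table.items() if hasattr(nda_table, "items") else nda_table
        self._nda: dict[str, str] = {
            normalize_nda(num): ingredient for num, ingredient in items
        }

        items = custom_mappings.items() if hasattr(custom_mappings, "items") else custom_mappings
        self._custom: dict[str, int] = {}
        for row_no, (name, cid) in enumerate(items, start=1):
            if cid not in self.concepts:
                raise VocabLoadError(
                    f"custom mapping row {row_no}: concept_id {cid} not loaded"
                )
            key = name.strip().lower()
            if key in self._custom:
                raise VocabLoadError(
                    f"custom mapping row {row_no}: duplicate name {name!r}"
                )
            self._custom[key] = cid

        self.crosswalk: list[AtcCrosswalkEntry] = []
        for row_no, entry in enumerate(crosswalk, start=1):
            if not ATC_CODE_RE.match(entry.atc_code):
                raise VocabLoadError(
                    f"crosswalk row {row_no}: bad ATC code {entry.atc_code!r}"
                )
            if (
                entry.strength_min is not None
                and entry.strength_max is not None
                and entry.strength_min > entry.strength_max
            ):
                raise VocabLoadError(
                    f"crosswalk row {row_no}: strength_min > strength_max"
                )
            self.crosswalk.append(entry)
        self._crosswalk_by_ingredient: dict[int, list[AtcCrosswalkEntry]] = {}
        for entry in self.crosswalk:
            self._crosswalk_by_ingredient.setdefault(
                entry.ingredient_concept_id, []
            ).append(entry)

    # ---- lookups --------------------------------------------------------

    def lookup_exact(
        self, name: str, include_synonyms: bool = True
    ) -> set[Concept]:
        """Concepts whose preferred term or any synonym equals the canonical
        form of ``name``; empty set when none."""
        key = self.normalizer.canonical_form(name)
        ids = set(self._preferred.get(key, ()))
        if include_synonyms:
            ids |= self._synonym.get(key, set())
        return {self.concepts[i] for i in ids}

    def brand_to_ingredient(self, name: str) -> str | None:
        """Brand-registry lookup (canonical form); the registered active
        ingredient name, or None."""
        return self._brands.get(self.normalizer.canonical_form(name))

    def nda_lookup(self, nda_num: str) -> str | None:
        """Ingredient registered for an application number (digits-only,
        leading zeros ignored), or None."""
        key = normalize_nda(nda_num)
        return self._nda.get(key) if key else None

    def custom_lookup(self, name: str) -> Concept | None:
        """Verbatim (case-insensitive, trimmed) custom-list lookup; no
        cleaning variants apply."""
        cid = self._custom.get(name.strip().lower())
        return self.concepts[cid] if cid is not None else None

    def out_edges(self, concept_id: int, kinds: Iterable[RelKind] | None = None):
        edges = self._out_edges.get(concept_id, [])
        if kinds is None:
            return list(edges)
        kindset = set(kinds)
        return [e for e in edges if e.kind in kindset]

    def drug_strengths(self, drug_concept_id: int) -> list[StrengthEntry]:
        return list(self._strength_by_drug.get(drug_concept_id, []))

    def crosswalk_for(self, ingredient_concept_id: int) -> list[AtcCrosswalkEntry]:
        return list(self._crosswalk_by_ingredient.get(ingredient_concept_id, []))

    def concepts_of_type(self, term_type: TermType) -> list[Concept]:
        return [c for c in self.concepts.values() if c.term_type is term_type]


def best_concept(concepts: Iterable[Concept]) -> Concept:
    """Deterministic tie-break among concepts matched by one name:
    standard before non-standard, STANDARD_DRUG before DRUG_EXTENSION,
    ingredient-most term type first, then lowest concept_id."""
    def rank(c: Concept):
        return (
            not c.standard,
            c.vocabulary is not Vocabulary.STANDARD_DRUG,
            _TT_RANK.get(c.term_type, 99),
            c.concept_id,
        )

    return min(concepts, key=rank)


# ---- file loading -------------------------------------------------------

DEFAULT_FILES = {
    "concept": "concept.tsv",
    "synonym": "synonym.tsv",
    "relationship": "relationship.tsv",
    "strength": "strength.tsv",
    "brand_registry": "brand_registry.tsv",
    "nda": "nda.tsv",
    "custom": "custom_mappings.tsv",
    "crosswalk": "atc_crosswalk.tsv",
}

_REQUIRED = ("concept",)


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise VocabLoadError(f"{path}: missing column(s) {', '.join(missing)}")


def load_vocab(
    directory: str | Path,
    sep: str = "\t",
    files: Mapping[str, str] | None = None,
    normalizer: Normalizer | None = None,
) -> VocabIndex:
    """Load the delimited vocabulary tables from ``directory`` into a
    :class:`VocabIndex`.

    Only ``concept.tsv`` is mandatory; every other table may be absent
    (treated as empty). Referential-integrity violations are fatal and name
    the offending rows.
    """
    directory = Path(directory)
    names = dict(DEFAULT_FILES)
    if files:
        names.update(files)

    def table(key: str, columns: tuple[str, ...]) -> pd.DataFrame:
        path = directory / names[key]
        if not path.exists():
            if key in _REQUIRED:
                raise VocabLoadError(f"required table not found: {path}")
            return pd.DataFrame(columns=list(columns))
        df = _read_table(path, sep)
        _require_columns(df, columns, path)
        return df

    cdf = table("concept", ("concept_id", "concept_name", "vocabulary", "term_type", "standard"))
    concepts = [
        Concept(
            concept_id=int(r.concept_id),
            name=r.concept_name,
            vocabulary=Vocabulary(r.vocabulary),
            term_type=TermType(r.term_type),
            standard=str(r.standard).strip().lower() in ("1", "true", "s", "yes"),
        )
        for r in cdf.itertuples(index=False)
    ]

    sdf = table("synonym", ("concept_id", "synonym"))
    synonyms = [(int(r.concept_id), r.synonym) for r in sdf.itertuples(index=False)]

    rdf = table("relationship", ("source_id", "target_id", "kind"))
    relationships = [
        Relationship(int(r.source_id), int(r.target_id), RelKind(r.kind))
        for r in rdf.itertuples(index=False)
    ]

    stdf = table("strength", ("drug_concept_id", "ingredient_concept_id", "amount", "unit"))
    strengths = [
        StrengthEntry(
            int(r.drug_concept_id), int(r.ingredient_concept_id),
            float(r.amount), r.unit,
        )
        for r in stdf.itertuples(index=False)
    ]

    bdf = table("brand_registry", ("brand", "ingredient_name"))
    brands = [(r.brand, r.ingredient_name) for r in bdf.itertuples(index=False)]

    ndf = table("nda", ("nda_num", "ingredient_name"))
    ndas = [(r.nda_num, r.ingredient_name) for r in ndf.itertuples(index=False)]

    mdf = table("custom", ("verbatim_name", "concept_id"))
    custom = [(r.verbatim_name, int(r.concept_id)) for r in mdf.itertuples(index=False)]

    xdf = table(
        "crosswalk",
        ("ingredient_concept_id", "atc_code", "route_class",
         "strength_min", "strength_max", "strength_unit"),
    )
    crosswalk = [
        AtcCrosswalkEntry(
            ingredient_concept_id=int(r.ingredient_concept_id),
            atc_code=r.atc_code,
            route_class=RouteClass(r.route_class) if r.route_class else RouteClass.ANY,
            strength_min=float(r.strength_min) if r.strength_min else None,
            strength_max=float(r.strength_max) if r.strength_max else None,
            strength_unit=r.strength_unit or None,
        )
        for r in xdf.itertuples(index=False)
    ]

    return VocabIndex(
        concepts=concepts,
        synonyms=synonyms,
        relationships=relationships,
        strengths=strengths,
        brand_registry=brands,
        nda_table=ndas,
        custom_mappings=custom,
        crosswalk=crosswalk,
        normalizer=normalizer,
    )
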