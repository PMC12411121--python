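"""Synthetic vocabularies, registries and FAERS drug files with planted
ground truth.

The generator is the oracle: every emitted drug record carries a
ground-truth row stating which cascade step must match it, which final
concept(s) it must map to, and which ATC code (if any) must be assigned.
The expectations are derived *analytically* from the planted noise and the
ledger of planted names — never by running the mapping pipeline — so a
full-corpus comparison of pipeline output against ground truth is a real
end-to-end check.

The vocabulary always plants the canonical hard cases:

* a route-split ingredient (timolol: C07AA06 oral vs S01ED01 ophthalmic);
* a strength-split ingredient (finasteride: D11AX10 low dose vs G04CB01
  high dose);
* an unspecific ingredient with several codes and no disambiguating
  evidence (calcium -> always abstain);
* a multi-ingredient combination with a crosswalk entry and one without;
* an ingredient missing from the crosswalk entirely;
* brands (in-vocabulary and registry-only), synonyms, NDA numbers and
  custom verbatim mappings.

Misspellings are single-character transpositions verified absent from
every index, so UNMAPPED expectations are sound by construction. The
ground truth is written to a separate file, never embedded in the FAERS
file, so the pipeline cannot cheat.

What this emulates — and what it does not: the noise model covers the
surface phenomena of FAERS free text (case, dosage/route suffixes,
parentheticals, punctuation, misspellings, missing fields) at configurable
rates; it does not model the reporting-frequency distribution of real
drugs, real-world vocabulary scale, or free-text pathologies outside the
planted taxonomy.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

from .normalize import Normalizer, default_normalizer
from .records import DrugRecord, write_drug_file
from .vocab import RouteClass

# ---------------------------------------------------------------------------
# specs and ledger types


@dataclass
class NoiseSpec:
    """Probabilities of the noise/scenario operations, all in [0, 1].

    Scenario probabilities (which cascade step a record is built to hit)
    and surface-noise probabilities (reversible decoration of the drug
    name) are drawn independently per record; the same seed reproduces
    byte-identical files.
    """

    # scenario selection (remaining mass -> plain name match, step 1)
    misspelling: float = 0.05
    prod_ai_only: float = 0.10
    nda_only: float = 0.05
    brand_substitution: float = 0.10
    word_split: float = 0.05
    custom_mapping: float = 0.04
    synonym_substitution: float = 0.10
    # surface noise on the drug name
    case_change: float = 0.30
    dosage_suffix: float = 0.25
    route_suffix: float = 0.20
    parenthetical: float = 0.15
    trailing_punct: float = 0.20
    # evidence fields
    missing_field: float = 0.35  # chance that route / dose evidence is absent
    dose_form_hint: float = 0.10  # route evidence via dose_form instead of route

    def validate(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"NoiseSpec.{f.name}={v} outside [0, 1]")
        scenario_mass = (
            self.misspelling + self.prod_ai_only + self.nda_only
            + self.brand_substitution + self.word_split + self.custom_mapping
            + self.synonym_substitution
        )
        if scenario_mass > 1.0:
            raise ValueError("scenario probabilities sum to more than 1")


@dataclass(frozen=True)
class CrosswalkRow:
    ingredient_id: int
    atc_code: str
    route_class: RouteClass = RouteClass.ANY
    strength_min: float | None = None
    strength_max: float | None = None
    strength_unit: str | None = "mg"


@dataclass(frozen=True)
class PlantedName:
    """One indexed name and the outcome it must produce when matched."""

    name: str
    concept_id: int
    final_ids: frozenset[int]  # ids after roll-up (expansion disabled)
    kind: str  # ingredient | multi | brand | synonym | clinical


@dataclass
class VocabLedger:
    """Everything the generator planted, for analytic expectation building."""

    names: list[PlantedName] = field(default_factory=list)
    registry: dict[str, tuple[str, int]] = field(default_factory=dict)  # brand -> (ing name, id)
    nda: dict[str, tuple[str, int]] = field(default_factory=dict)
    custom: dict[str, tuple[int, frozenset[int]]] = field(default_factory=dict)
    crosswalk: list[CrosswalkRow] = field(default_factory=list)
    combo_pairs: dict[frozenset[int], int] = field(default_factory=dict)  # ingredient ids -> multi id
    ingredient_names: dict[int, str] = field(default_factory=dict)
    indexed_canonicals: set[str] = field(default_factory=set)
    row_counts: dict[str, int] = field(default_factory=dict)

    def crosswalk_for(self, concept_id: int) -> list[CrosswalkRow]:
        return [r for r in self.crosswalk if r.ingredient_id == concept_id]


@dataclass(frozen=True)
class GroundTruth:
    """Fixtures-only expectation for one generated record."""

    line_no: int
    report_id: str
    scenario: str
    noise_ops: tuple[str, ...]
    expected_step: int | None  # None == UNMAPPED
    expected_final_ids: frozenset[int]
    expected_atc: str | None


# ---------------------------------------------------------------------------
# vocabulary generation

_SYLLABLES = [
    "bar", "vel", "dor", "mex", "tal", "zon", "pir", "lam", "cet", "rin",
    "fos", "nab", "qui", "sor", "tev", "ulm", "vax", "wex", "yol", "zan",
]

_ROUTE_TOKENS = {
    RouteClass.ORAL: ["ORAL", "PO", "SUBLINGUAL"],
    RouteClass.OPHTHALMIC: ["OPHTHALMIC", "INTRAOCULAR"],
    RouteClass.TOPICAL: ["TOPICAL", "TRANSDERMAL", "CUTANEOUS"],
    RouteClass.PARENTERAL: ["INTRAVENOUS", "INTRAMUSCULAR", "SUBCUTANEOUS"],
    RouteClass.INHALATION: ["INHALATION", "INHALED"],
    RouteClass.RECTAL: ["RECTAL"],
    RouteClass.NASAL: ["NASAL", "INTRANASAL"],
    RouteClass.VAGINAL: ["VAGINAL"],
    RouteClass.OTHER: ["OTIC", "INTRATHECAL"],
}

_DOSAGE_SUFFIXES = ["10MG", "20MG", "40MG", "100MG", "250MG", "500MG", "0.5%", "2%"]
_ROUTE_SUFFIXES = ["ORAL", "TABLETS", "CAPSULE", "INJECTION", "TOPICAL", "SOLUTION"]
_PARENTHETICALS = ["(UNKNOWN)", "(FOR PAIN)", "(1 TABLET DAILY)", "(PATIENT REPORTED)"]
_TRAILERS = ["...", ".", " .", ".."]


class FixtureError(ValueError):
    """Infeasible size parameters or an internal planting collision."""


def _pseudo_name(rng: random.Random, taken: set[str], norm: Normalizer) -> str:
    for _ in range(1000):
        n = rng.randint(3, 4)
        name = "".join(rng.choice(_SYLLABLES) for _ in range(n))
        if norm.canonical_form(name) not in taken:
            return name
    raise FixtureError("could not generate a fresh pseudo name")


def _pseudo_atc(rng: random.Random, taken: set[str]) -> str:
    for _ in range(1000):
        code = (
            rng.choice("ABCDGHJLMNPRSV")
            + f"{rng.randint(1, 99):02d}"
            + rng.choice("ABCDEFX") + rng.choice("ABCDEFX")
            + f"{rng.randint(1, 99):02d}"
        )
        if code not in taken:
            taken.add(code)
            return code
    raise FixtureError("could not generate a fresh ATC code")


def generate_vocabulary(
    out_dir: str | Path,
    seed: int = 0,
    n_filler_ingredients: int = 12,
    n_filler_brands: int = 6,
    n_registry_brands: int = 8,
    n_nda: int = 8,
    n_custom: int = 4,
    normalizer: Normalizer | None = None,
) -> VocabLedger:
    """Write a referentially intact toy vocabulary file set and return its
    ledger. Deterministic for a given seed (byte-identical files)."""
    if n_filler_ingredients < 0 or n_registry_brands < 1 or n_nda < 1 or n_custom < 1:
        raise FixtureError("size parameters below feasible minimum")
    rng = random.Random(seed)
    norm = normalizer or default_normalizer()
    canon = norm.canonical_form
    ledger = VocabLedger()
    taken_canon: set[str] = set()
    taken_atc: set[str] = set()

    concepts: list[tuple[int, str, str, str, str]] = []
    synonyms: list[tuple[int, str]] = []
    relationships: list[tuple[int, int, str]] = []
    strengths: list[tuple[int, int, float, str]] = []

    next_id = [100]

    def new_id() -> int:
        next_id[0] += 1
        return next_id[0]

    def plant_concept(name, vocabulary, term_type, standard=True) -> int:
        cid = new_id()
        key = canon(name)
        if key in taken_canon and term_type != "DOSE_FORM":
            raise FixtureError(f"name collision while planting {name!r}")
        taken_canon.add(key)
        concepts.append((cid, name, vocabulary, term_type, "1" if standard else "0"))
        return cid

    def plant_name(name, cid, final_ids, kind):
        ledger.names.append(PlantedName(name, cid, frozenset(final_ids), kind))

    def plant_ingredient(name) -> int:
        cid = plant_concept(name, "STANDARD_DRUG", "INGREDIENT")
        ledger.ingredient_names[cid] = name
        plant_name(name, cid, {cid}, "ingredient")
        return cid

    # --- core ingredients (the planted hard cases) ----------------------
    timolol = plant_ingredient("timolol")
    finasteride = plant_ingredient("finasteride")
    diltiazem = plant_ingredient("diltiazem")
    omeprazole = plant_ingredient("omeprazole")
    pantoprazole = plant_ingredient("pantoprazole")
    smx = plant_ingredient("sulfamethoxazole")
    tmp = plant_ingredient("trimethoprim")
    calcium = plant_ingredient("calcium")
    aspirin = plant_ingredient("aspirin")
    sulfasalazine = plant_ingredient("sulfasalazine")
    acetaminophen = plant_ingredient("acetaminophen")
    amlodipine = plant_ingredient("amlodipine")
    benazepril = plant_ingredient("benazepril")
    guaifenesin = plant_ingredient("guaifenesin")  # deliberately no crosswalk row

    core_atc = [
        CrosswalkRow(timolol, "C07AA06", RouteClass.ORAL),
        CrosswalkRow(timolol, "S01ED01", RouteClass.OPHTHALMIC),
        CrosswalkRow(finasteride, "D11AX10", RouteClass.ANY, 0.5, 1.0, "mg"),
        CrosswalkRow(finasteride, "G04CB01", RouteClass.ANY, 2.0, 10.0, "mg"),
        CrosswalkRow(diltiazem, "C08DB01"),
        CrosswalkRow(omeprazole, "A02BC01"),
        CrosswalkRow(pantoprazole, "A02BC02"),
        CrosswalkRow(smx, "J01EC01"),
        CrosswalkRow(tmp, "J01EA01"),
        CrosswalkRow(calcium, "A12AA20"),
        CrosswalkRow(calcium, "B05XA07"),
        CrosswalkRow(calcium, "D11AX03"),
        CrosswalkRow(aspirin, "B01AC06", RouteClass.ANY, 25.0, 325.0, "mg"),
        CrosswalkRow(aspirin, "N02BA01", RouteClass.ANY, 326.0, 1000.0, "mg"),
        CrosswalkRow(sulfasalazine, "A07EC01"),
        CrosswalkRow(acetaminophen, "N02BE01"),
        CrosswalkRow(amlodipine, "C08CA01"),
        CrosswalkRow(benazepril, "C09AA07"),
    ]
    taken_atc.update(r.atc_code for r in core_atc)
    ledger.crosswalk.extend(core_atc)

    # --- multi-ingredient combinations ----------------------------------
    m1 = plant_concept("sulfamethoxazole / trimethoprim", "STANDARD_DRUG", "MULTI_INGREDIENT")
    relationships += [(m1, smx, "CONSISTS_OF"), (m1, tmp, "CONSISTS_OF")]
    plant_name("sulfamethoxazole / trimethoprim", m1, {m1}, "multi")
    ledger.crosswalk.append(CrosswalkRow(m1, "J01EE01"))
    taken_atc.add("J01EE01")
    ledger.combo_pairs[frozenset({smx, tmp})] = m1

    m2 = plant_concept("amlodipine / benazepril", "STANDARD_DRUG", "MULTI_INGREDIENT")
    relationships += [(m2, amlodipine, "CONSISTS_OF"), (m2, benazepril, "CONSISTS_OF")]
    plant_name("amlodipine / benazepril", m2, {m2}, "multi")
    ledger.combo_pairs[frozenset({amlodipine, benazepril})] = m2
    # no crosswalk row for m2: concept maps, ATC must abstain

    # --- in-vocabulary brands -------------------------------------------
    for brand_name, ingredient_ids in [
        ("cardizem", [diltiazem]),
        ("tylenol", [acetaminophen]),
        ("proscar", [finasteride]),
        ("bactrim", [smx, tmp]),
    ]:
        bid = plant_concept(brand_name, "STANDARD_DRUG", "BRAND_NAME")
        for iid in ingredient_ids:
            relationships.append((bid, iid, "HAS_INGREDIENT"))
        if len(ingredient_ids) >= 2:
            final = {ledger.combo_pairs[frozenset(ingredient_ids)]}
        else:
            final = set(ingredient_ids)
        plant_name(brand_name, bid, final, "brand")

    # --- dose forms and clinical drug (forms) ---------------------------
    oral_tablet = plant_concept("Oral Tablet", "STANDARD_DRUG", "DOSE_FORM")
    eye_drops = plant_concept("Eye Drops", "STANDARD_DRUG", "DOSE_FORM")

    cd = plant_concept("finasteride 5 MG Oral Tablet", "STANDARD_DRUG", "CLINICAL_DRUG")
    relationships += [(cd, finasteride, "HAS_INGREDIENT"), (cd, oral_tablet, "HAS_DOSE_FORM")]
    strengths.append((cd, finasteride, 5.0, "mg"))
    plant_name("finasteride 5 MG Oral Tablet", cd, {finasteride}, "clinical")

    cdf = plant_concept("finasteride Oral Tablet", "STANDARD_DRUG", "CLINICAL_DRUG_FORM")
    relationships += [(cdf, finasteride, "HAS_INGREDIENT"), (cdf, oral_tablet, "HAS_DOSE_FORM")]
    plant_name("finasteride Oral Tablet", cdf, {finasteride}, "clinical")

    tdf = plant_concept("timolol Ophthalmic Solution", "STANDARD_DRUG", "CLINICAL_DRUG_FORM")
    relationships += [(tdf, timolol, "HAS_INGREDIENT"), (tdf, eye_drops, "HAS_DOSE_FORM")]
    plant_name("timolol Ophthalmic Solution", tdf, {timolol}, "clinical")

    # --- filler ingredients and brands ----------------------------------
    filler_ids: list[int] = []
    for i in range(n_filler_ingredients):
        name = _pseudo_name(rng, taken_canon, norm)
        cid = plant_ingredient(name)
        filler_ids.append(cid)
        if i % 4 == 3:
            # route-split filler, like timolol
            ledger.crosswalk.append(
                CrosswalkRow(cid, _pseudo_atc(rng, taken_atc), RouteClass.ORAL)
            )
            ledger.crosswalk.append(
                CrosswalkRow(cid, _pseudo_atc(rng, taken_atc), RouteClass.TOPICAL)
            )
        else:
            ledger.crosswalk.append(CrosswalkRow(cid, _pseudo_atc(rng, taken_atc)))

    for i in range(n_filler_brands):
        name = _pseudo_name(rng, taken_canon, norm)
        target = rng.choice(filler_ids) if filler_ids else diltiazem
        bid = plant_concept(name, "DRUG_EXTENSION", "BRAND_NAME")
        relationships.append((bid, target, "HAS_INGREDIENT"))
        plant_name(name, bid, {target}, "brand")

    # --- synonyms --------------------------------------------------------
    synonym_sources = [timolol, finasteride, diltiazem, aspirin, *filler_ids[:4]]
    for cid in synonym_sources:
        base = ledger.ingredient_names[cid]
        text = base + "um"
        if canon(text) in taken_canon:
            text = base + "ix"
        if canon(text) in taken_canon:
            continue
        taken_canon.add(canon(text))
        synonyms.append((cid, text))
        plant_name(text, cid, {cid}, "synonym")

    # --- registry-only brands (Article-57-like) -------------------------
    registry_targets = [timolol, finasteride, omeprazole, aspirin, *filler_ids]
    for i in range(n_registry_brands):
        name = _pseudo_name(rng, taken_canon, norm)
        taken_canon.add(canon(name))  # reserve: registry brands are indexed too
        target = registry_targets[i % len(registry_targets)]
        ledger.registry[name.upper()] = (ledger.ingredient_names[target], target)

    # --- NDA table -------------------------------------------------------
    nda_targets = [finasteride, diltiazem, pantoprazole, *filler_ids]
    nda_seen: set[str] = set()
    while len(ledger.nda) < n_nda:
        num = str(rng.randint(10000, 99999))
        if num in nda_seen:
            continue
        nda_seen.add(num)
        target = nda_targets[len(ledger.nda) % len(nda_targets)]
        ledger.nda[num] = (ledger.ingredient_names[target], target)

    # --- custom verbatim mappings ---------------------------------------
    custom_targets = [omeprazole, pantoprazole, calcium, *filler_ids]
    while len(ledger.custom) < n_custom:
        phrase = (
            _pseudo_name(rng, taken_canon, norm).upper()
            + " "
            + _pseudo_name(rng, taken_canon, norm).upper()
        )
        if canon(phrase) in taken_canon:
            continue
        for token in phrase.split():
            taken_canon.add(canon(token))  # keep tokens out of future names
        taken_canon.add(canon(phrase))
        target = custom_targets[len(ledger.custom) % len(custom_targets)]
        ledger.custom[phrase] = (target, frozenset({target}))

    ledger.indexed_canonicals = set(taken_canon)

    # --- write the file set ---------------------------------------------
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def write(name: str, header: list[str], rows: list[tuple]) -> None:
        with open(out_dir / name, "w", encoding="utf-8", newline="") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")
        ledger.row_counts[name] = len(rows)

    write("concept.tsv",
          ["concept_id", "concept_name", "vocabulary", "term_type", "standard"],
          concepts)
    write("synonym.tsv", ["concept_id", "synonym"], synonyms)
    write("relationship.tsv", ["source_id", "target_id", "kind"], relationships)
    write("strength.tsv",
          ["drug_concept_id", "ingredient_concept_id", "amount", "unit"],
          strengths)
    write("brand_registry.tsv", ["brand", "ingredient_name"],
          [(b, ing) for b, (ing, _) in ledger.registry.items()])
    write("nda.tsv", ["nda_num", "ingredient_name"],
          [(n, ing) for n, (ing, _) in ledger.nda.items()])
    write("custom_mappings.tsv", ["verbatim_name", "concept_id"],
          [(p, cid) for p, (cid, _) in ledger.custom.items()])
    write("atc_crosswalk.tsv",
          ["ingredient_concept_id", "atc_code", "route_class",
           "strength_min", "strength_max", "strength_unit"],
          [(r.ingredient_id, r.atc_code, r.route_class.value,
            r.strength_min, r.strength_max, r.strength_unit)
           for r in ledger.crosswalk])
    return ledger


# ---------------------------------------------------------------------------
# FAERS file generation with analytic ground truth


def _misspell(name: str, rng: random.Random, forbidden: set[str],
              norm: Normalizer) -> str:
    """Single-character transposition verified absent from every index."""
    letters = [c for c in name if c.isalpha()]
    if len(letters) < 4:
        name = name + "x"
    for _ in range(200):
        chars = list(name)
        positions = [i for i in range(len(chars) - 1)
                     if chars[i].isalpha() and chars[i + 1].isalpha()
                     and chars[i].lower() != chars[i + 1].lower()]
        if not positions:
            chars.insert(rng.randrange(len(chars)), rng.choice("qxz"))
        else:
            i = rng.choice(positions)
            chars[i], chars[i + 1] = chars[i + 1], chars[i]
        out = "".join(chars)
        if _is_junk(out, forbidden, norm):
            return out
    raise FixtureError(f"could not produce a verified misspelling of {name!r}")


def _is_junk(name: str, forbidden: set[str], norm: Normalizer) -> bool:
    """True when no cleaned variant and no token of ``name`` is indexed."""
    variants = [v for _, v in norm.clean_cascade(name)] or [name]
    for variant in variants:
        if norm.canonical_form(variant) in forbidden:
            return False
        for token in variant.split():
            if norm.canonical_form(token) in forbidden:
                return False
    return True


def _junk_token(rng: random.Random, forbidden: set[str], norm: Normalizer) -> str:
    for _ in range(1000):
        token = "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 3)))
        token = token.upper()
        if len(token) >= 3 and _is_junk(token, forbidden, norm):
            return token
    raise FixtureError("could not generate a junk token")


def perturb_name(
    name: str, noise: NoiseSpec, rng: random.Random
) -> tuple[str, tuple[str, ...]]:
    """Apply sampled reversible surface-noise operations in fixed order;
    returns (noisy name, ops applied). Zero noise is the identity."""
    ops: list[str] = []
    out = name
    if rng.random() < noise.case_change:
        out = out.upper() if rng.random() < 0.7 else out.lower()
        ops.append("case_change")
    if rng.random() < noise.dosage_suffix:
        out = f"{out} {rng.choice(_DOSAGE_SUFFIXES)}"
        ops.append("dosage_suffix")
    if rng.random() < noise.route_suffix:
        out = f"{out} {rng.choice(_ROUTE_SUFFIXES)}"
        ops.append("route_suffix")
    if rng.random() < noise.parenthetical:
        out = f"{out} {rng.choice(_PARENTHETICALS)}"
        ops.append("parenthetical")
    if rng.random() < noise.trailing_punct:
        out = out + rng.choice(_TRAILERS)
        ops.append("trailing_punct")
    return out, tuple(ops)


def _expected_atc(
    ledger: VocabLedger,
    final_ids: frozenset[int],
    route_class: RouteClass,
    strength_mg: float | None,
) -> str | None:
    """Analytic replica of the abstention rule: unique surviving crosswalk
    entry after narrowing filters (a filter that empties the set is
    ignored), else None."""
    if len(final_ids) != 1:
        return None
    candidates = ledger.crosswalk_for(next(iter(final_ids)))
    if not candidates:
        return None
    if route_class not in (RouteClass.UNKNOWN, RouteClass.ANY):
        narrowed = [c for c in candidates
                    if c.route_class in (RouteClass.ANY, route_class)]
        if narrowed:
            candidates = narrowed
    if strength_mg is not None:
        def ok(c: CrosswalkRow) -> bool:
            if c.strength_min is not None and strength_mg < c.strength_min * 0.99:
                return False
            if c.strength_max is not None and strength_mg > c.strength_max * 1.01:
                return False
            return True

        narrowed = [c for c in candidates if ok(c)]
        if narrowed:
            candidates = narrowed
    return candidates[0].atc_code if len(candidates) == 1 else None


def _pick_evidence(
    rng: random.Random,
    noise: NoiseSpec,
    final_ids: frozenset[int],
    ledger: VocabLedger,
) -> tuple[str | None, str | None, str | None, str | None, RouteClass, float | None]:
    """Choose route/dose fields for a record and return both the raw field
    values and the evidence the generator knows they encode."""
    route_field = dose_amt = dose_unit = dose_form = None
    route_class = RouteClass.UNKNOWN
    strength: float | None = None
    if len(final_ids) != 1:
        return route_field, dose_amt, dose_unit, dose_form, route_class, strength
    rows = ledger.crosswalk_for(next(iter(final_ids)))
    if not rows:
        return route_field, dose_amt, dose_unit, dose_form, route_class, strength

    target = rng.choice(rows)
    # route evidence
    if target.route_class is not RouteClass.ANY and rng.random() >= noise.missing_field:
        if target.route_class is RouteClass.OPHTHALMIC and rng.random() < noise.dose_form_hint:
            dose_form = "EYE DROPS"
            route_class = RouteClass.OPHTHALMIC
        else:
            route_field = rng.choice(_ROUTE_TOKENS[target.route_class])
            route_class = target.route_class
    # strength evidence
    if target.strength_min is not None and rng.random() >= noise.missing_field:
        lo = target.strength_min
        hi = target.strength_max if target.strength_max is not None else lo * 2
        amount = round(rng.uniform(lo, hi), 1)
        if amount == int(amount):
            amount = int(amount)
        dose_amt = str(amount)
        dose_unit = "MG"
        strength = float(amount)
    return route_field, dose_amt, dose_unit, dose_form, route_class, strength


def generate_faers_file(
    out_path: str | Path,
    n: int,
    ledger: VocabLedger,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    gt_path: str | Path | None = None,
    normalizer: Normalizer | None = None,
) -> tuple[list[DrugRecord], list[GroundTruth]]:
    """Generate ``n`` FAERS drug-file records plus their ground truth.

    Writes the drug file to ``out_path`` and (optionally) the ground-truth
    table to ``gt_path``; also returns both in memory.
    """
    noise = noise or NoiseSpec()
    noise.validate()
    rng = random.Random(seed)
    norm = normalizer or default_normalizer()
    forbidden = ledger.indexed_canonicals

    name_targets = [p for p in ledger.names if p.kind in
                    ("ingredient", "multi", "brand", "synonym")]
    single_token_ingredients = [
        p for p in ledger.names
        if p.kind == "ingredient" and len(p.name.split()) == 1 and len(p.name) >= 3
    ]
    registry_brands = list(ledger.registry.items())
    nda_numbers = list(ledger.nda.items())
    custom_phrases = list(ledger.custom.items())

    records: list[DrugRecord] = []
    truths: list[GroundTruth] = []

    for i in range(n):
        report_id = f"R{seed}{i:06d}"
        drug_seq = "1"
        u = rng.random()
        thresholds = [
            ("misspelling", noise.misspelling),
            ("prod_ai", noise.prod_ai_only),
            ("nda", noise.nda_only),
            ("brand_registry", noise.brand_substitution),
            ("word_split", noise.word_split),
            ("custom", noise.custom_mapping),
            ("synonym", noise.synonym_substitution),
        ]
        scenario = "name"
        acc = 0.0
        for label, p in thresholds:
            acc += p
            if u < acc:
                scenario = label
                break

        drugname = prod_ai = route_f = dose_amt = dose_unit = dose_form = nda_num = None
        ops: tuple[str, ...] = ()
        expected_step: int | None = None
        final_ids: frozenset[int] = frozenset()

        if scenario == "misspelling":
            base = rng.choice(single_token_ingredients)
            drugname = _misspell(base.name.upper(), rng, forbidden, norm)
            expected_step = None
            ops = ("misspelling",)

        elif scenario == "prod_ai":
            junk_or_missing = rng.random()
            if junk_or_missing < 0.4:
                drugname = None
            else:
                drugname = _junk_token(rng, forbidden, norm)
                ops = ("junk_drugname",)
            roll = rng.random()
            if roll < 0.2:
                # known combination -> multi concept
                ids, multi_id = rng.choice(
                    sorted(ledger.combo_pairs.items(), key=lambda kv: kv[1])
                )
                a, b = sorted(ids)
                prod_ai = (
                    ledger.ingredient_names[a].upper()
                    + "\\" + ledger.ingredient_names[b].upper()
                )
                final_ids = frozenset({multi_id})
            elif roll < 0.35:
                # unknown combination -> two single ingredients, ATC abstains
                a, b = rng.sample([p.concept_id for p in single_token_ingredients], 2)
                while frozenset({a, b}) in ledger.combo_pairs:
                    a, b = rng.sample(
                        [p.concept_id for p in single_token_ingredients], 2
                    )
                prod_ai = (
                    ledger.ingredient_names[a].upper()
                    + ";" + ledger.ingredient_names[b].upper()
                )
                final_ids = frozenset({a, b})
            else:
                target = rng.choice(single_token_ingredients)
                prod_ai = target.name.upper()
                final_ids = target.final_ids
            expected_step = 2

        elif scenario == "nda":
            drugname = _junk_token(rng, forbidden, norm) if rng.random() < 0.6 else None
            num, (ing_name, iid) = rng.choice(nda_numbers)
            nda_num = num if rng.random() < 0.5 else "0" + num
            final_ids = frozenset({iid})
            expected_step = 4

        elif scenario == "brand_registry":
            brand, (ing_name, iid) = rng.choice(registry_brands)
            drugname, ops = perturb_name(brand, noise, rng)
            final_ids = frozenset({iid})
            expected_step = 3

        elif scenario == "word_split":
            target = rng.choice(single_token_ingredients)
            junk = _junk_token(rng, forbidden, norm)
            drugname = f"{junk} {target.name.upper()}"
            final_ids = target.final_ids
            expected_step = 5
            ops = ("word_split",)

        elif scenario == "custom":
            phrase, (cid, fids) = rng.choice(custom_phrases)
            drugname = phrase if rng.random() < 0.7 else phrase.lower()
            final_ids = fids
            expected_step = 6

        else:
            if scenario == "synonym":
                pool = [p for p in name_targets if p.kind == "synonym"]
            else:
                pool = [p for p in name_targets if p.kind != "synonym"]
            target = rng.choice(pool)
            drugname, ops = perturb_name(target.name.upper(), noise, rng)
            final_ids = target.final_ids
            expected_step = 1

        # evidence fields and expected ATC
        if expected_step is not None:
            atc_lookup_ids = final_ids
            route_f, dose_amt, dose_unit, dose_form, route_class, strength = (
                _pick_evidence(rng, noise, atc_lookup_ids, ledger)
            )
            expected_atc = _expected_atc(ledger, atc_lookup_ids, route_class, strength)
        else:
            expected_atc = None

        record = DrugRecord(
            report_id=report_id,
            drug_seq=drug_seq,
            drugname=drugname,
            prod_ai=prod_ai,
            route=route_f,
            dose_amt=dose_amt,
            dose_unit=dose_unit,
            dose_form=dose_form,
            nda_num=nda_num,
        )
        records.append(record)
        truths.append(GroundTruth(
            line_no=i + 2,  # header is line 1
            report_id=report_id,
            scenario=scenario,
            noise_ops=ops,
            expected_step=expected_step,
            expected_final_ids=final_ids,
            expected_atc=expected_atc,
        ))

    write_drug_file(records, out_path)
    if gt_path is not None:
        with open(gt_path, "w", encoding="utf-8", newline="") as fh:
            fh.write("line_no\treport_id\tscenario\tnoise_ops\texpected_step\t"
                     "expected_final_ids\texpected_atc\n")
            for t in truths:
                fh.write("\t".join([
                    str(t.line_no),
                    t.report_id,
                    t.scenario,
                    ",".join(t.noise_ops),
                    "UNMAPPED" if t.expected_step is None else str(t.expected_step),
                    ";".join(str(c) for c in sorted(t.expected_final_ids)),
                    t.expected_atc or "",
                ]) + "\n")
    return records, truths
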