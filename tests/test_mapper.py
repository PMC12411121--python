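"""Cascade semantics: step order, stop-on-first-success, word split,
custom list, determinism and the brute-force oracle."""

import random

import pytest

from conftest import concept_by_name
from faersnorm.atc import assign_atc
from faersnorm.fixtures import NoiseSpec, generate_faers_file
from faersnorm.mapper import (
    ALL_STEPS,
    MapOptions,
    custom_lookup,
    map_record,
    map_records,
    word_split_match,
)
from faersnorm.records import DrugRecord
from faersnorm.rollup import finalize
from faersnorm.vocab import TermType, best_concept


def ids(concepts):
    return {c.concept_id for c in concepts}


class TestCascadeSteps:
    def test_preferred_term_matches_at_step_1(self, index):
        res = map_record(DrugRecord(drugname="TIMOLOL"), index)
        assert res.matched_step == 1
        assert ids(res.final_concepts) == ids({concept_by_name(index, "timolol")})

    def test_misspelling_with_no_fallback_is_unmapped(self, index):
        res = map_record(DrugRecord(drugname="CARDIAZEM"), index)
        assert res.matched_step is None
        assert res.raw_concepts == frozenset() == res.final_concepts

    def test_prod_ai_rescues_unmatchable_drugname(self, index):
        res = map_record(
            DrugRecord(drugname="ZZZNOSUCH", prod_ai="TIMOLOL"), index)
        assert res.matched_step == 2

    def test_multi_prod_ai_resolves_to_combination_concept(self, index):
        res = map_record(
            DrugRecord(prod_ai="SULFAMETHOXAZOLE\\TRIMETHOPRIM"), index)
        assert res.matched_step == 2
        (final,) = res.final_concepts
        assert final.term_type is TermType.MULTI_INGREDIENT

    def test_partial_prod_ai_match_is_flagged(self, index):
        res = map_record(
            DrugRecord(prod_ai="TIMOLOL\\ZZZNOTHING"), index)
        assert res.matched_step == 2
        assert any("partial" in n for n in res.notes)

    def test_brand_registry_at_step_3(self, index, ledger):
        brand, (_, iid) = next(iter(ledger.registry.items()))
        res = map_record(DrugRecord(drugname=brand), index)
        assert res.matched_step == 3
        assert ids(res.final_concepts) == {iid}

    def test_nda_number_at_step_4(self, index, ledger):
        num, (_, iid) = next(iter(ledger.nda.items()))
        res = map_record(DrugRecord(drugname="ZZZNOSUCH", nda_num=num), index)
        assert res.matched_step == 4
        assert ids(res.final_concepts) == {iid}

    def test_custom_list_at_step_6(self, index, ledger):
        phrase, (cid, _) = next(iter(ledger.custom.items()))
        res = map_record(DrugRecord(drugname=phrase), index)
        assert res.matched_step == 6

    def test_stop_on_first_success(self, index):
        # a name matchable at several steps stops at the earliest one, and
        # the audit trail shows later steps were never consulted
        res = map_record(DrugRecord(drugname="timolol"), index)
        assert res.matched_step == 1
        assert not any("step 5" in n or "step 6" in n for n in res.notes)

    def test_all_missing_record_is_unmapped(self, index):
        res = map_record(DrugRecord(), index)
        assert res.matched_step is None


class TestWordSplit:
    def test_known_token_inside_junk(self, index):
        hits = word_split_match("UNKNOWNBRANDX ASPIRIN KIT", index)
        assert ids(hits) == ids({concept_by_name(index, "aspirin")})

    def test_all_tokens_unknown(self, index):
        assert word_split_match("ZZZFOO QQQBAR", index) == set()

    def test_short_tokens_and_stopwords_skipped(self, index):
        # "ca" is too short to be looked up even if a concept matched it
        assert word_split_match("CA AND FOR", index) == set()

    def test_ingredient_priority_over_brand(self):
        # one token matching both an ingredient and a brand yields the
        # ingredient hit only
        from faersnorm.vocab import Concept, TermType, VocabIndex, Vocabulary
        concepts = [
            Concept(1, "xalotan", Vocabulary.STANDARD_DRUG, TermType.BRAND_NAME, True),
            Concept(2, "latanoprost", Vocabulary.STANDARD_DRUG, TermType.INGREDIENT, True),
        ]
        idx = VocabIndex(concepts, synonyms=[(2, "xalotan")])
        hits = word_split_match("xalotan", idx)
        assert ids(hits) == {2}


class TestCustomLookup:
    def test_verbatim_case_insensitive_trimmed(self, index, ledger):
        phrase, (cid, _) = next(iter(ledger.custom.items()))
        assert custom_lookup(index, f"  {phrase.lower()} ").concept_id == cid

    def test_no_cleaning_variants_applied(self, index, ledger):
        phrase, _ = next(iter(ledger.custom.items()))
        assert custom_lookup(index, phrase + " 500MG") is None

    def test_empty_custom_list(self):
        from faersnorm.vocab import Concept, TermType, VocabIndex, Vocabulary
        idx = VocabIndex([Concept(1, "a", Vocabulary.STANDARD_DRUG,
                                  TermType.INGREDIENT, True)])
        assert custom_lookup(idx, "anything") is None


@pytest.fixture(scope="module")
def corpus(tmp_path_factory, ledger):
    out = tmp_path_factory.mktemp("corpus")
    return generate_faers_file(out / "drug.txt", 400, ledger, seed=11)


class TestCascadeProperties:
    def test_determinism_under_record_shuffle(self, index, corpus):
        records, _ = corpus
        shuffled = records[:]
        random.Random(5).shuffle(shuffled)
        a = map_records(records, index)
        b = map_records(shuffled, index)
        assert a.keys() == b.keys()
        for key in a:
            assert a[key].matched_step == b[key].matched_step
            assert a[key].final_concepts == b[key].final_concepts

    def test_disabling_any_step_never_increases_coverage(self, index, corpus):
        records, _ = corpus
        full = sum(1 for r in map_records(records, index).values() if r.mapped)
        for step in sorted(ALL_STEPS):
            opts = MapOptions(enabled_steps=ALL_STEPS - {step})
            reduced = sum(
                1 for r in map_records(records, index, opts).values() if r.mapped
            )
            assert reduced <= full, f"disabling step {step} raised coverage"

    def test_synonym_matching_never_decreases_coverage(self, index, corpus):
        records, _ = corpus
        with_syn = sum(
            1 for r in map_records(records, index,
                                   MapOptions(use_synonyms=True)).values()
            if r.mapped)
        without = sum(
            1 for r in map_records(records, index,
                                   MapOptions(use_synonyms=False)).values()
            if r.mapped)
        assert with_syn >= without

    def test_agrees_with_brute_force_matcher(self, index, corpus):
        """Exhaustive reference: try every (variant, resource) pair, then
        order successes by (step, variant ordinal) and take the first."""
        records, _ = corpus
        norm = index.normalizer
        for record in records[:200]:
            attempts = []  # (step, variant_ordinal) for every success
            cascade = (norm.clean_cascade(record.drugname)
                       if record.drugname is not None else [])
            for vi, (_, variant) in enumerate(cascade):
                hits = index.lookup_exact(variant)
                if hits and finalize({best_concept(hits)}, index):
                    attempts.append((1, vi))
            if record.prod_ai is not None:
                import re
                parts = [p for p in re.split(r"[\\;]", record.prod_ai) if p.strip()]
                matched = set()
                for part in parts:
                    for _, variant in norm.clean_cascade(part):
                        hits = index.lookup_exact(variant)
                        if hits:
                            matched.add(best_concept(hits))
                            break
                if matched and finalize(matched, index):
                    attempts.append((2, 0))
            for vi, (_, variant) in enumerate(cascade):
                ing = index.brand_to_ingredient(variant)
                if ing and index.lookup_exact(ing):
                    attempts.append((3, vi))
            if record.nda_num is not None:
                ing = index.nda_lookup(record.nda_num)
                if ing and index.lookup_exact(ing):
                    attempts.append((4, 0))
            if cascade and word_split_match(cascade[-1][1], index):
                attempts.append((5, 0))
            if record.drugname is not None and index.custom_lookup(record.drugname):
                attempts.append((6, 0))

            expected_step = min(attempts)[0] if attempts else None
            got = map_record(record, index)
            assert got.matched_step == expected_step, record
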