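import pytest

from phenorec.lexicon import Dictionary, WordLists
from phenorec.rules import (
    CandidateEntity,
    RuleConfig,
    rule_entity_variations,
    rule_general_errors,
    rule_incorrect_structure,
    rule_longer_entities,
    rule_negative_connotation,
    rule_second_validation,
    rule_smaller_entities,
    rule_stop_words,
    validate,
)

from conftest import make_doc


@pytest.fixture()
def wl(word_lists):
    return word_lists


def _cand(doc_text, surface, origin="crf", doc_id="d1"):
    start = doc_text.index(surface)
    return CandidateEntity(doc_id, start, start + len(surface), surface, origin)


def _dict(*entries):
    d = Dictionary()
    for e in entries:
        d.add(e, {"HP_0000001"}, "test")
    return d


class TestEntityVariations:
    def test_abnormalities_of_the_ear(self, wl):
        doc, sents = make_doc("Severe abnormalities of the ear were found.")
        cands = rule_entity_variations(sents[0], doc.text, wl)
        assert [c.surface for c in cands] == ["abnormalities of the ear"]

    def test_coordinated_adjective_group(self, wl):
        doc, sents = make_doc("We saw defects of the outer, middle, and inner ear.")
        cands = rule_entity_variations(sents[0], doc.text, wl)
        assert [c.surface for c in cands] == ["defects of the outer, middle, and inner ear"]

    def test_no_common_noun_no_candidates(self, wl):
        doc, sents = make_doc("The patient walked to the clinic.")
        assert rule_entity_variations(sents[0], doc.text, wl) == []


class TestLongerEntities:
    def test_spine_and_rib_anomalies(self, wl):
        doc, sents = make_doc("Severe spine and rib anomalies were noted.")
        seed = _cand(doc.text, "rib anomalies")
        out = rule_longer_entities(sents[0], doc.text, [seed], _dict(), wl)
        assert "spine and rib anomalies" in {c.surface for c in out}
        assert all(c.origin == "expansion" for c in out)

    def test_sentence_start_without_coordination_unchanged(self, wl):
        doc, sents = make_doc("Rib anomalies were noted.")
        seed = _cand(doc.text, "Rib anomalies")
        assert rule_longer_entities(sents[0], doc.text, [seed], _dict(), wl) == []

    def test_constructed_x_and_y(self, wl):
        doc, sents = make_doc("There were skull and femur anomalies at birth.")
        seed = _cand(doc.text, "femur anomalies")
        out = rule_longer_entities(sents[0], doc.text, [seed], _dict(), wl)
        assert "skull and femur anomalies" in {c.surface for c in out}

    def test_rightward_expansion(self, wl):
        doc, sents = make_doc("He had pits of the palms and soles.")
        seed = _cand(doc.text, "pits of the palms")
        out = rule_longer_entities(sents[0], doc.text, [seed], _dict(), wl)
        assert "pits of the palms and soles" in {c.surface for c in out}

    def test_removed_candidates_ignored(self, wl):
        doc, sents = make_doc("Severe spine and rib anomalies were noted.")
        seed = _cand(doc.text, "rib anomalies").removed("test")
        assert rule_longer_entities(sents[0], doc.text, [seed], _dict(), wl) == []


class TestSmallerEntities:
    def test_pits_of_the_palms_and_soles(self, wl):
        doc, _ = make_doc("He had pits of the palms and soles.")
        parent = _cand(doc.text, "pits of the palms and soles")
        out = rule_smaller_entities([parent], wl)
        assert "pits of the palms" in {c.surface for c in out}
        assert parent.status == "active"  # parent retained

    def test_no_coordination_unchanged(self, wl):
        doc, _ = make_doc("He had renal dysplasia there.")
        assert rule_smaller_entities([_cand(doc.text, "renal dysplasia")], wl) == []

    def test_distribution_flag(self, wl):
        doc, _ = make_doc("He had pits of the palms and soles.")
        parent = _cand(doc.text, "pits of the palms and soles")
        out = rule_smaller_entities([parent], wl, distribute=True)
        assert {c.surface for c in out} == {"pits of the palms", "pits of the soles"}

    def test_coordinated_modifier_split(self, wl):
        doc, _ = make_doc("Severe spine and rib anomalies were noted.")
        parent = _cand(doc.text, "spine and rib anomalies")
        out = rule_smaller_entities([parent], wl)
        assert "rib anomalies" in {c.surface for c in out}


class TestSecondValidation:
    def test_nothing_new_adds_nothing(self, wl):
        doc, sents = make_doc("The patient was well.")
        assert rule_second_validation(sents, doc.text, [], _dict(), wl, RuleConfig()) == []

    def test_pass_two_variation_match(self, wl):
        # pass 1 identifies "abnormalities of the kidney" (head-noun rule);
        # pass 2 treats it as a dictionary entry, whose generated variation
        # "kidney abnormalities" then matches in the second sentence
        doc, sents = make_doc(
            "Imaging showed abnormalities of the kidney. "
            "The kidney abnormalities persisted."
        )
        final, audit = validate([], doc, sents, Dictionary(), wl)
        origins = {c.surface: c.origin for c in audit}
        assert origins["kidney abnormalities"] == "second_pass"
        assert any(c.surface == "kidney abnormalities" for c in final)

    def test_third_pass_fixed_point(self, wl):
        doc, sents = make_doc(
            "Imaging showed abnormalities of the kidney. "
            "The kidney abnormalities persisted."
        )
        _final, audit = validate([], doc, sents, Dictionary(), wl)
        third = rule_second_validation(sents, doc.text, audit, Dictionary(), wl,
                                       RuleConfig())
        assert {c.span for c in third} <= {c.span for c in audit}


class TestGeneralErrors:
    @pytest.mark.parametrize(
        "surface,reason",
        [
            ("36", "digit_only"),
            ("ab", "too_short"),
            ("abnormalities and malformations", "multiple_common_nouns"),
            ("broken (paren", "unbalanced_quote_or_paren"),
        ],
    )
    def test_removals(self, wl, surface, reason):
        cand = CandidateEntity("d", 0, len(surface), surface, "crf")
        (out,) = rule_general_errors([cand], wl)
        assert out.status == "removed" and out.removal_reason == reason

    def test_valid_candidate_kept(self, wl):
        cand = CandidateEntity("d", 0, 15, "renal dysplasia", "crf")
        (out,) = rule_general_errors([cand], wl)
        assert out.status == "active"


class TestIncorrectStructure:
    @pytest.mark.parametrize("surface", ["anomalies of", "anomalies of the",
                                         "anomalies,", "anomalies."])
    def test_bad_final_token_removed(self, surface):
        cand = CandidateEntity("d", 0, len(surface), surface, "crf")
        (out,) = rule_incorrect_structure([cand])
        assert out.status == "removed" and out.removal_reason == "bad_final_token"

    def test_renal_dysplasia_kept(self):
        cand = CandidateEntity("d", 0, 15, "renal dysplasia", "crf")
        (out,) = rule_incorrect_structure([cand])
        assert out.status == "active"


class TestNegativeConnotation:
    def test_cognitive_development_removed(self, wl):
        cand = CandidateEntity("d", 0, 21, "cognitive development", "crf")
        (out,) = rule_negative_connotation([cand], wl)
        assert out.status == "removed" and out.removal_reason == "positive_connotation"

    def test_three_tokens_kept(self, wl):
        cand = CandidateEntity("d", 0, 32, "cognitive development impairment", "crf")
        (out,) = rule_negative_connotation([cand], wl)
        assert out.status == "active"

    def test_two_tokens_without_listed_noun_kept(self, wl):
        cand = CandidateEntity("d", 0, 15, "renal dysplasia", "crf")
        (out,) = rule_negative_connotation([cand], wl)
        assert out.status == "active"


class TestStopWords:
    def test_exact_match_removed(self, wl):
        cand = CandidateEntity("d", 0, 11, "hippocampus", "crf")
        (out,) = rule_stop_words([cand], wl)
        assert out.status == "removed" and out.removal_reason == "stop_exact"

    def test_exact_list_does_not_remove_longer_phrase(self, wl):
        cand = CandidateEntity("d", 0, 20, "enlarged hippocampus", "crf")
        (out,) = rule_stop_words([cand], wl)
        assert out.status == "active"

    def test_partial_match_removes_longer_phrase(self):
        lists = WordLists(stop_partial=["hippocampus"])
        cand = CandidateEntity("d", 0, 20, "enlarged hippocampus", "crf")
        (out,) = rule_stop_words([cand], lists)
        assert out.status == "removed" and out.removal_reason == "stop_partial"


class TestValidatePipeline:
    def test_empty_inputs(self, wl):
        doc, sents = make_doc("Nothing to see here.")
        final, audit = validate([], doc, sents, Dictionary(), wl)
        assert final == [] and audit == []

    def test_all_rules_disabled_is_identity(self, wl):
        doc, sents = make_doc("He showed renal dysplasia and hippocampus issues.")
        spans = [(10, 25, "renal dysplasia"), (30, 41, "hippocampus")]
        final, _ = validate(spans, doc, sents, _dict("renal dysplasia"), wl,
                            RuleConfig.none())
        assert [(c.start, c.end) for c in final] == [(10, 25), (30, 41)]
        assert all(c.origin == "crf" for c in final)

    def test_leading_digit_trim(self, wl):
        doc, sents = make_doc("We counted 36 schwannomas in total.")
        start = doc.text.index("36 schwannomas")
        final, audit = validate(
            [(start, start + 14, "36 schwannomas")], doc, sents, Dictionary(), wl)
        surfaces = {c.surface for c in final}
        assert "schwannomas" in surfaces
        assert "36 schwannomas" not in surfaces
        trimmed = next(c for c in audit if c.surface == "36 schwannomas")
        assert trimmed.removal_reason == "leading_digit_trimmed"

    def test_every_removed_has_reason_and_counts_reconcile(self, wl):
        doc, sents = make_doc(
            "The 36 patients had pits of the palms and soles and cognitive development.")
        start = doc.text.index("pits")
        final, audit = validate(
            [(start, start + len("pits of the palms and soles"),
              "pits of the palms and soles"), (4, 6, "36")],
            doc, sents, _dict("pits of the palms and soles"), wl)
        removed = [c for c in audit if c.status == "removed"]
        assert all(c.removal_reason for c in removed)
        assert len(final) + len(removed) == len(audit)

    def test_identification_rules_never_remove(self, wl, toy_bundle):
        from phenorec.preprocess import preprocess_document

        for doc in toy_bundle.corpus.documents[:3]:
            sents = preprocess_document(doc)
            gold = toy_bundle.corpus.annotations_for(doc.doc_id)
            spans = [(a.start, a.end, a.surface) for a in gold]
            d = _dict(*[a.surface for a in gold])
            base, _ = validate(spans, doc, sents, d, wl, RuleConfig.none())
            ident, _ = validate(spans, doc, sents, d, wl, RuleConfig.identification_only())
            assert {c.span for c in base} <= {c.span for c in ident}

    def test_removal_rules_never_add(self, wl, toy_bundle):
        from phenorec.preprocess import preprocess_document

        for doc in toy_bundle.corpus.documents[:3]:
            sents = preprocess_document(doc)
            gold = toy_bundle.corpus.annotations_for(doc.doc_id)
            spans = [(a.start, a.end, a.surface) for a in gold]
            d = _dict(*[a.surface for a in gold])
            base, _ = validate(spans, doc, sents, d, wl, RuleConfig.none())
            removal, _ = validate(spans, doc, sents, d, wl, RuleConfig.removal_only())
            assert {c.span for c in removal} <= {c.span for c in base}

    def test_golden_pipeline_trace(self, wl):
        # one document exercising every rule once; expected output hand-traced
        doc, sents = make_doc(
            "He had pits of the palms and soles. "
            "The hippocampus appeared intact. "
            "Cognitive development was typical. "
            "We measured 36 things."
        )
        crf_spans = [
            (doc.text.index("hippocampus"), doc.text.index("hippocampus") + 11,
             "hippocampus"),
            (doc.text.index("Cognitive"), doc.text.index("development") + 11,
             "Cognitive development"),
            (doc.text.index("36"), doc.text.index("36") + 2, "36"),
        ]
        d = _dict("pits of the palms and soles")
        final, audit = validate(crf_spans, doc, sents, d, wl)
        assert {c.surface for c in final} == {
            "pits of the palms and soles",  # dictionary
            "pits of the palms",            # smaller-entities split
        }
        reasons = {c.surface: c.removal_reason for c in audit if c.status == "removed"}
        assert reasons["hippocampus"] == "stop_exact"
        assert reasons["Cognitive development"] == "positive_connotation"
        assert reasons["36"] == "digit_only"
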