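import itertools
import random

import pytest
from hypothesis import given, strategies as st

from phenorec.corpus import AnnotationRecord, Corpus, DocumentRecord, diff_corpora
from phenorec.evaluate import (
    Score,
    build_gsc_plus,
    filter_false_positives,
    inconsistency_report,
    score,
)
from phenorec.lexicon import Dictionary, build_dictionary


def _ann(doc, start, end, hpo="HP_0000001", surface=None):
    return AnnotationRecord(doc, start, end, hpo, surface or "x" * (end - start))


class TestScore:
    def test_identical_sets_are_perfect(self, toy_bundle):
        s = score(toy_bundle.corpus.annotations, toy_bundle.corpus.annotations)
        assert (s.precision, s.recall, s.f_measure) == (1.0, 1.0, 1.0)

    def test_f_measure_formula_consistency(self):
        # counts engineered to give P = 0.65 and R = 0.49 exactly
        s = Score(tp=637, fp=343, fn=663)
        assert s.precision == pytest.approx(0.65)
        assert s.recall == pytest.approx(0.49)
        assert s.f_measure == pytest.approx(0.56, abs=0.005)

    def test_three_predicted_two_gold_one_overlap(self):
        predicted = [_ann("d", 0, 5), _ann("d", 10, 15), _ann("d", 20, 25)]
        gold = [_ann("d", 0, 5), _ann("d", 30, 35)]
        # brute-force oracle: count exact span-key pairs
        tp = sum(
            1 for p, g in itertools.product(predicted, gold)
            if p.span_key == g.span_key
        )
        assert tp == 1
        s = score(predicted, gold)
        assert s.precision == pytest.approx(1 / 3)
        assert s.recall == pytest.approx(1 / 2)
        assert s.f_measure == pytest.approx(0.4)

    def test_empty_denominators_are_zero(self):
        s = score([], [])
        assert (s.precision, s.recall, s.f_measure) == (0.0, 0.0, 0.0)

    def test_id_strict_mode(self):
        predicted = [_ann("d", 0, 5, "HP_0000001")]
        gold = [_ann("d", 0, 5, "HP_0000002")]
        assert score(predicted, gold).tp == 1
        assert score(predicted, gold, id_strict=True).tp == 0

    @given(st.integers(0, 500))
    def test_symmetric_under_swap(self, seed):
        rng = random.Random(seed)
        mk = lambda: [
            _ann("d", i * 10, i * 10 + 5)
            for i in range(rng.randint(0, 8)) if rng.random() < 0.6
        ]
        a, b = mk(), mk()
        assert score(a, b).precision == pytest.approx(score(b, a).recall)
        assert score(a, b).f_measure == pytest.approx(score(b, a).f_measure)


class TestFilterFalsePositives:
    def _dictionary(self, *surfaces):
        d = Dictionary()
        for s in surfaces:
            d.add(s, {"HP_0000001"}, "test")
        return d

    def test_tumours_example(self):
        text_pos = (0, 7)
        pred = [_ann("d", *text_pos, surface="tumours")]
        filtered = filter_false_positives(pred, [], self._dictionary("tumours"))
        assert filtered == []

    def test_gold_prediction_retained_regardless(self):
        pred = [_ann("d", 0, 7, surface="tumours")]
        gold = [_ann("d", 0, 7, surface="tumours")]
        assert filter_false_positives(pred, gold, self._dictionary("tumours")) == pred

    def test_non_dictionary_fp_retained(self):
        pred = [_ann("d", 0, 7, surface="tumours")]
        assert filter_false_positives(pred, [], Dictionary()) == pred

    @given(st.integers(0, 500))
    def test_recall_invariance(self, seed):
        rng = random.Random(seed)
        surfaces = ["alpha", "beta", "gamma", "delta"]
        gold = [
            _ann("d", i * 10, i * 10 + 5, surface=rng.choice(surfaces))
            for i in range(5) if rng.random() < 0.7
        ]
        pred = [
            _ann("d", i * 10, i * 10 + 5, surface=rng.choice(surfaces))
            for i in range(8) if rng.random() < 0.7
        ]
        d = self._dictionary(*rng.sample(surfaces, k=rng.randint(0, 4)))
        filtered = filter_false_positives(pred, gold, d)
        before, after = score(pred, gold), score(filtered, gold)
        assert after.recall == pytest.approx(before.recall)
        assert after.tp == before.tp and after.fn == before.fn
        assert after.f_measure >= before.f_measure - 1e-12


class TestBuildGscPlus:
    def test_already_annotated_span_not_duplicated(self, tiny_ontology):
        doc = DocumentRecord("d", "tumours were seen in the patient cohort.")
        gold = [_ann("d", 0, 7, "HP_0100526", "tumours")]
        corpus = Corpus([doc], gold)
        extended, additions = build_gsc_plus(corpus, gold, tiny_ontology)
        assert additions == []
        assert len(extended.annotations) == 1

    def test_qualifying_predictions_added(self, toy_bundle):
        corpus = toy_bundle.corpus
        preds = [
            AnnotationRecord(m.doc_id, m.start, m.end, m.hpo_id, m.surface)
            for m in toy_bundle.unannotated_mentions()
        ]
        extended, additions = build_gsc_plus(corpus, preds, toy_bundle.ontology)
        assert len(additions) == len(preds)
        d = diff_corpora(corpus, extended)
        assert len(d.added) == len(preds) and not d.removed and not d.modified

    def test_unverifiable_prediction_not_added(self, tiny_ontology):
        doc = DocumentRecord("d", "wibble wobble was seen here today okay.")
        corpus = Corpus([doc], [])
        pred = [_ann("d", 0, 13, "HP_0000001", "wibble wobble")]
        _extended, additions = build_gsc_plus(corpus, pred, tiny_ontology)
        assert additions == []

    def test_nested_superclass_mention_added(self, tiny_ontology):
        # only the longer mention is annotated; the nested superclass
        # "tumours" matches the ontology and is appended
        text = "Multiple intracranial tumours were found early."
        doc = DocumentRecord("d", text)
        start = text.index("intracranial")
        gold = [
            AnnotationRecord("d", start, start + len("intracranial tumours"),
                             "HP_0004375", "intracranial tumours")
        ]
        corpus = Corpus([doc], gold)
        t_start = text.index("tumours")
        pred = [AnnotationRecord("d", t_start, t_start + 7, "HP_0100526", "tumours")]
        _extended, additions = build_gsc_plus(corpus, pred, tiny_ontology)
        assert [a.surface for a in additions] == ["tumours"]

    def test_output_is_valid_corpus(self, toy_bundle):
        preds = [
            AnnotationRecord(m.doc_id, m.start, m.end, m.hpo_id, m.surface)
            for m in toy_bundle.unannotated_mentions()
        ]
        extended, _ = build_gsc_plus(toy_bundle.corpus, preds, toy_bundle.ontology)
        for ann in extended.annotations:
            assert extended.text_of(ann.doc_id)[ann.start : ann.end] == ann.surface


class TestInconsistencyReport:
    def test_count_inconsistency_three_vs_two(self, tiny_ontology):
        text = ("Renal dysplasia was seen. Later renal dysplasia worsened. "
                "Finally renal dysplasia stabilised.")
        doc = DocumentRecord("d", text)
        spans = []
        at = 0
        for _ in range(3):
            i = text.lower().index("renal dysplasia", at)
            spans.append((i, i + 15))
            at = i + 1
        anns = [
            AnnotationRecord("d", s, e, "HP_0000110", text[s:e])
            for s, e in spans[:2]  # annotate only two of three occurrences
        ]
        report = inconsistency_report(Corpus([doc], anns), tiny_ontology)
        hits = [h for h in report.annotation_counts if h["surface"] == "renal dysplasia"]
        assert hits and hits[0]["occurrences"] == 3 and hits[0]["annotated"] == 2

    def test_consistent_corpus_empty_report(self, tiny_ontology):
        text = "Renal dysplasia was seen once."
        doc = DocumentRecord("d", text)
        anns = [AnnotationRecord("d", 0, 15, "HP_0000110", "Renal dysplasia")]
        report = inconsistency_report(Corpus([doc], anns), tiny_ontology)
        assert report.is_empty()

    def test_nested_unannotated_dictionary_surface(self, tiny_ontology):
        # "spine and rib anomalies" has "rib anomalies" annotated too;
        # "skin and genital anomalies" lacks the nested "genital anomalies"
        text_ok = "We saw spine and rib anomalies there."
        text_bad = "We saw skin and genital anomalies there."
        d_ok = DocumentRecord("ok", text_ok)
        d_bad = DocumentRecord("bad", text_bad)
        full_ok = (7, 7 + len("spine and rib anomalies"))
        nested_ok = (text_ok.index("rib anomalies"), text_ok.index("rib anomalies") + 13)
        full_bad = (7, 7 + len("skin and genital anomalies"))
        anns = [
            AnnotationRecord("ok", *full_ok, "HP_0000002", "spine and rib anomalies"),
            AnnotationRecord("ok", *nested_ok, "HP_0000003", "rib anomalies"),
            AnnotationRecord("bad", *full_bad, "HP_0000078", "skin and genital anomalies"),
        ]
        dictionary = Dictionary()
        for s in ("spine and rib anomalies", "rib anomalies",
                  "skin and genital anomalies", "genital anomalies"):
            dictionary.add(s, {"HP_0000099"}, "test")
        report = inconsistency_report(
            Corpus([d_ok, d_bad], anns), tiny_ontology, dictionary)
        nested_docs = {h["doc_id"] for h in report.nested_entities}
        assert "bad" in nested_docs
        bad_hits = [h for h in report.nested_entities if h["doc_id"] == "bad"]
        assert {h["nested_surface"] for h in bad_hits} == {"genital anomalies"}
        assert "ok" not in nested_docs

    def test_fixture_annotations_all_have_meaning(self, toy_bundle):
        # every fixture annotation stems from the ontology or its variations,
        # so the entity-meaning class must be empty
        report = inconsistency_report(toy_bundle.corpus, toy_bundle.ontology)
        assert report.entity_meaning == []

    def test_build_dictionary_backing(self, toy_bundle):
        d = build_dictionary(toy_bundle.ontology, toy_bundle.corpus.annotations)
        report = inconsistency_report(toy_bundle.corpus, toy_bundle.ontology, d)
        assert report.total >= 0
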