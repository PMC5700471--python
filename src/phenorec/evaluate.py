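"""Exact-span evaluation and corpus-consistency tooling.

Scoring is micro-averaged over documents with the span key
``(doc_id, start, end)``; requiring accession equality as well is a flag.
Also implements the false-positive-filter experiment (drop non-gold
predictions whose surface exists in a phenotype dictionary — recall is
unchanged by construction), extension of a gold corpus with verified
predictions, and a four-class annotation-inconsistency report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

from phenorec.corpus import AnnotationRecord, Corpus, Ontology
from phenorec.lexicon import Dictionary, normalize_surface

__all__ = [
    "Score",
    "score",
    "filter_false_positives",
    "build_gsc_plus",
    "inconsistency_report",
    "InconsistencyReport",
]


@dataclass(frozen=True)
class Score:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(precision=self.precision, recall=self.recall, f_measure=self.f_measure)
        return d

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)


def _keys(annotations: Iterable[AnnotationRecord], id_strict: bool) -> set:
    if id_strict:
        return {a.full_key for a in annotations}
    return {a.span_key for a in annotations}


def score(
    predicted: Sequence[AnnotationRecord],
    gold: Sequence[AnnotationRecord],
    id_strict: bool = False,
) -> Score:
    """Micro-averaged exact-span precision/recall/F over all documents."""
    pred_keys = _keys(predicted, id_strict)
    gold_keys = _keys(gold, id_strict)
    tp = len(pred_keys & gold_keys)
    return Score(tp=tp, fp=len(pred_keys - gold_keys), fn=len(gold_keys - pred_keys))


def filter_false_positives(
    predicted: Sequence[AnnotationRecord],
    gold: Sequence[AnnotationRecord],
    dictionary: Dictionary,
) -> list[AnnotationRecord]:
    """Drop non-gold predictions whose surface exists in the dictionary.

    Predictions matching a gold span are always kept, so true positives and
    false negatives — and therefore recall — are unchanged; F cannot drop.
    """
    gold_keys = {a.span_key for a in gold}
    return [
        p
        for p in predicted
        if p.span_key in gold_keys or p.surface not in dictionary
    ]


def build_gsc_plus(
    corpus: Corpus,
    predicted: Sequence[AnnotationRecord],
    ontology: Ontology,
    strict_case: bool = False,
) -> tuple[Corpus, list[AnnotationRecord]]:
    """Extend a gold corpus with verified predictions.

    A prediction is appended when its surface exact-matches an ontology name
    or synonym or an existing annotation surface, and its span is not already
    annotated.  Matching is case-insensitive with whitespace normalization
    unless ``strict_case``.  Returns the extended corpus and the additions.
    """
    norm = (lambda s: " ".join(s.split())) if strict_case else normalize_surface

    known_surfaces: dict[str, set[str]] = {}
    for surface, hpo_id, _src in ontology.surface_forms():
        known_surfaces.setdefault(norm(surface), set()).add(hpo_id)
    for ann in corpus.annotations:
        known_surfaces.setdefault(norm(ann.surface), set()).add(ann.hpo_id)

    annotated_spans = {a.span_key for a in corpus.annotations}
    additions: list[AnnotationRecord] = []
    seen: set[tuple[str, int, int]] = set()
    for pred in predicted:
        if pred.span_key in annotated_spans or pred.span_key in seen:
            continue
        ids = known_surfaces.get(norm(pred.surface))
        if not ids:
            continue
        hpo_id = pred.hpo_id if pred.hpo_id in ids else sorted(ids)[0]
        additions.append(AnnotationRecord(
            pred.doc_id, pred.start, pred.end, hpo_id, pred.surface))
        seen.add(pred.span_key)

    extended = Corpus(list(corpus.documents), list(corpus.annotations) + additions)
    return extended, additions


@dataclass
class InconsistencyReport:
    """Per-class suspect annotations (see ``inconsistency_report``)."""

    annotation_counts: list[dict]
    entity_meaning: list[AnnotationRecord]
    nested_entities: list[dict]
    superclass_subclass: list[dict]

    @property
    def total(self) -> int:
        return (len(self.annotation_counts) + len(self.entity_meaning)
                + len(self.nested_entities) + len(self.superclass_subclass))

    def is_empty(self) -> bool:
        return self.total == 0


def _occurrence_spans(text: str, surface: str) -> list[tuple[int, int]]:
    """Word-boundary case-insensitive occurrences of a surface in text."""
    import re

    words = [re.escape(w) for w in surface.split()]
    pat = re.compile(r"(?<!\w)" + r"\s+".join(words) + r"(?!\w)", re.IGNORECASE)
    return [(m.start(), m.end()) for m in pat.finditer(text)]


def inconsistency_report(corpus: Corpus, ontology: Ontology,
                         dictionary: Dictionary | None = None) -> InconsistencyReport:
    """Audit a gold corpus for the four annotation-inconsistency classes.

    1. *annotation counts* — a surface annotated in some but not all of its
       occurrences within a document;
    2. *entity meaning* — annotated surfaces matching no ontology name,
       synonym, or generated variation;
    3. *nested entities* — annotated surfaces containing an unannotated
       dictionary surface;
    4. *superclass/subclass* — a subclass mention whose superclass surface
       occurs elsewhere in the document unannotated.
    """
    if dictionary is None:
        from phenorec.lexicon import build_dictionary

        dictionary = build_dictionary(ontology, corpus.annotations, generate=True)

    ontology_surfaces = {
        normalize_surface(s) for s, _hid, _src in ontology.surface_forms()
    }
    dict_surfaces = set(dictionary.entries)

    counts: list[dict] = []
    meaning: list[AnnotationRecord] = []
    nested: list[dict] = []
    superclass: list[dict] = []

    for doc in corpus.documents:
        anns = corpus.annotations_for(doc.doc_id)
        ann_spans = {a.span_key[1:] for a in anns}
        surfaces_annotated = {normalize_surface(a.surface) for a in anns}

        # class 1: per-surface occurrence vs annotation counts
        for surface in sorted(surfaces_annotated):
            occ = _occurrence_spans(doc.text, surface)
            n_ann = sum(1 for a in anns if normalize_surface(a.surface) == surface)
            if len(occ) > n_ann:
                counts.append({
                    "doc_id": doc.doc_id, "surface": surface,
                    "occurrences": len(occ), "annotated": n_ann,
                })

        for ann in anns:
            norm = normalize_surface(ann.surface)
            # class 2: surface unknown to the ontology (incl. variations)
            if norm not in dict_surfaces:
                meaning.append(ann)
            # class 3: an unannotated dictionary surface nested inside
            inner = [
                w for w in dict_surfaces
                if w != norm and f" {w} " in f" {norm} "
            ]
            for w in sorted(inner):
                for s, e in _occurrence_spans(doc.text, w):
                    if ann.start <= s and e <= ann.end and (s, e) not in ann_spans:
                        nested.append({
                            "doc_id": doc.doc_id, "annotation": ann,
                            "nested_surface": w, "start": s, "end": e,
                        })
            # class 4: superclass surface occurring elsewhere, unannotated
            head = norm.split(" of ")[0] if " of " in norm else norm.split()[-1]
            if head != norm and head in ontology_surfaces:
                for s, e in _occurrence_spans(doc.text, head):
                    outside = not (ann.start <= s and e <= ann.end)
                    if outside and (s, e) not in ann_spans:
                        superclass.append({
                            "doc_id": doc.doc_id, "annotation": ann,
                            "superclass_surface": head, "start": s, "end": e,
                        })

    return InconsistencyReport(counts, meaning, nested, superclass)
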