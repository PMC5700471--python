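"""Self-contained synthetic test fixtures.

Generates a toy phenotype ontology (OBO), a gold corpus in the offset
annotation format, rule word-lists, and a machine-readable ledger of every
planted phenomenon: which mentions were annotated, which were deliberately
left unannotated, where coordination / variation / nesting was injected, and
which distractor phrases were planted.  Everything is deterministic given the
seed, and the entity vocabulary is disjoint from the background vocabulary so
the sequence labeler is learnable at tiny scale.

Vocabulary comes from a small closed template grammar (body parts ×
abnormality nouns × modifiers) so dictionary variations are generable and
checkable by hand.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from phenorec.corpus import AnnotationRecord, Corpus, DocumentRecord, Ontology, write_corpus
from phenorec.lexicon import WordLists

__all__ = ["FixtureSpec", "FixtureBundle", "PlantedMention", "generate_fixture"]

_PARTS = ["kidney", "ear", "spine", "rib", "palm", "sole", "liver", "retina",
          "skull", "femur", "aorta", "thumb", "elbow", "cornea", "tongue"]
_AB_NOUNS = [("abnormality", "abnormalities"), ("malformation", "malformations"),
             ("anomaly", "anomalies"), ("defect", "defects"), ("pit", "pits")]
_SIMPLE_TERMS = ["microcephaly", "seizures", "scoliosis", "nystagmus", "ataxia",
                 "clinodactyly"]

_BACKGROUND = [
    "The study followed several families over two years.",
    "Informed consent was obtained from all participants.",
    "Genetic testing confirmed the diagnosis in most cases.",
    "Clinical records were reviewed by two independent observers.",
    "The molecular basis remains unknown in half of the cohort.",
    "Follow-up visits were scheduled at regular intervals.",
]

_MENTION_TEMPLATES = [
    ("Examination revealed ", " during early infancy."),
    ("The patient presented with ", " at birth."),
    ("Radiographs showed ", " on both sides."),
    ("We observed ", " in three siblings."),
]


@dataclass
class FixtureSpec:
    n_terms: int = 10
    n_docs: int = 8
    seed: int = 0
    variation_rate: float = 0.5
    coordination_rate: float = 0.5
    nesting_rate: float = 0.5
    unannotated_rate: float = 0.3
    positive_distractor_rate: float = 0.3
    stop_distractor_rate: float = 0.3

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name.endswith("_rate") and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_terms < 4 or self.n_docs < 1:
            raise ValueError("need at least 4 terms and 1 document")


@dataclass
class PlantedMention:
    doc_id: str
    start: int
    end: int
    surface: str
    hpo_id: str
    annotated: bool
    phenomenon: str  # plain | variation | coordination | nested | unannotated


@dataclass
class FixtureBundle:
    ontology: Ontology
    corpus: Corpus
    word_lists: WordLists
    mentions: list[PlantedMention] = field(default_factory=list)
    distractors: list[dict] = field(default_factory=list)

    @property
    def ledger(self) -> dict:
        return {
            "mentions": [asdict(m) for m in self.mentions],
            "distractors": self.distractors,
        }

    def unannotated_mentions(self) -> list[PlantedMention]:
        return [m for m in self.mentions if not m.annotated]


def _build_ontology(spec: FixtureSpec, rng: random.Random):
    """Toy ontology: compound 'X of the <part>' terms (some with a rewritten
    synonym) plus a few single-word terms; returns (ontology, term table)."""
    terms: dict[str, str] = {"HP_0000001": "phenotypic abnormality",
                             "HP_0000077": "Abnormality of the kidney"}
    synonyms: dict[str, set[str]] = {}
    parents: dict[str, set[str]] = {"HP_0000077": {"HP_0000001"}}

    n_compound = max(3, int(spec.n_terms * 0.7))
    table = []  # (hpo_id, name, part, noun_pl or None)
    for i in range(spec.n_terms):
        hpo_id = f"HP_{9000001 + i:07d}"
        if i < n_compound:
            part = _PARTS[i % len(_PARTS)]
            _sg, pl = _AB_NOUNS[i % len(_AB_NOUNS)]
            name = f"{pl} of the {part}"
            terms[hpo_id] = name
            if rng.random() < 0.5:
                synonyms[hpo_id] = {f"{part} {pl}"}
            table.append((hpo_id, name, part, pl))
        else:
            name = _SIMPLE_TERMS[(i - n_compound) % len(_SIMPLE_TERMS)]
            terms[hpo_id] = name
            table.append((hpo_id, name, None, None))
        parents[hpo_id] = {"HP_0000001"}
    return Ontology(terms, synonyms, parents), table


def _ontology_to_obo(ontology: Ontology) -> str:
    lines = ["format-version: 1.2", "ontology: toy-phenotype", ""]
    for hpo_id in sorted(ontology.terms):
        lines += ["[Term]", f"id: HP:{hpo_id.split('_')[1]}"]
        lines.append(f"name: {ontology.terms[hpo_id]}")
        for syn in sorted(ontology.synonyms.get(hpo_id, ())):
            lines.append(f'synonym: "{syn}" EXACT []')
        for parent in sorted(ontology.parents.get(hpo_id, ())):
            lines.append(f"is_a: HP:{parent.split('_')[1]}")
        lines.append("")
    return "\n".join(lines)


class _DocBuilder:
    def __init__(self, doc_id: str) -> None:
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.length = 0

    def add_sentence(self, prefix: str, mention: str = "", suffix: str = "") -> int:
        """Append one sentence; returns the document offset of the mention."""
        if self.parts:
            self.parts.append(" ")
            self.length += 1
        offset = self.length + len(prefix)
        sentence = prefix + mention + suffix
        self.parts.append(sentence)
        self.length += len(sentence)
        return offset

    @property
    def text(self) -> str:
        return "".join(self.parts)


def generate_fixture(spec: FixtureSpec, out_dir: str | Path | None = None) -> FixtureBundle:
    """Build the fixture bundle; optionally write it to disk.

    On-disk layout: ``ontology.obo``, ``docs/``, ``anns/``, ``word_lists/``
    and ``ledger.json`` under ``out_dir``.
    """
    rng = random.Random(spec.seed)
    ontology, table = _build_ontology(spec, rng)
    compound = [t for t in table if t[2] is not None]
    word_lists = WordLists.default()

    mentions: list[PlantedMention] = []
    distractors: list[dict] = []
    documents: list[DocumentRecord] = []
    annotations: list[AnnotationRecord] = []

    for d in range(spec.n_docs):
        doc_id = f"{10000 + d}"
        builder = _DocBuilder(doc_id)
        builder.add_sentence(rng.choice(_BACKGROUND))

        def plant(surface: str, hpo_id: str, annotated: bool, phenomenon: str,
                  template=None) -> int:
            prefix, suffix = template or rng.choice(_MENTION_TEMPLATES)
            off = builder.add_sentence(prefix, surface, suffix)
            mentions.append(PlantedMention(
                doc_id, off, off + len(surface), surface, hpo_id, annotated, phenomenon))
            if annotated:
                annotations.append(AnnotationRecord(
                    doc_id, off, off + len(surface), hpo_id, surface))
            return off

        # one or two plain mentions of term names
        for _ in range(rng.randint(1, 2)):
            hpo_id, name, _p, _n = table[rng.randrange(len(table))]
            plant(name, hpo_id, True, "plain")

        # rewritten variation: "<part> <nouns>" for a compound term
        if rng.random() < spec.variation_rate:
            hpo_id, _name, part, noun_pl = compound[rng.randrange(len(compound))]
            plant(f"{part} {noun_pl}", hpo_id, True, "variation")

        # coordination: "<partA> and <partB> <nouns>", optionally nested
        if rng.random() < spec.coordination_rate:
            hpo_id, _name, part_b, noun_pl = compound[rng.randrange(len(compound))]
            others = [p for p in _PARTS if p != part_b]
            part_a = others[rng.randrange(len(others))]
            coord = f"{part_a} and {part_b} {noun_pl}"
            off = plant(coord, hpo_id, True, "coordination")
            if rng.random() < spec.nesting_rate:
                sub = f"{part_b} {noun_pl}"
                sub_off = off + len(coord) - len(sub)
                mentions.append(PlantedMention(
                    doc_id, sub_off, sub_off + len(sub), sub, hpo_id, True, "nested"))
                annotations.append(AnnotationRecord(
                    doc_id, sub_off, sub_off + len(sub), hpo_id, sub))

        # deliberately unannotated mention of a term name
        if rng.random() < spec.unannotated_rate:
            hpo_id, name, _p, _n = table[rng.randrange(len(table))]
            plant(name, hpo_id, False, "unannotated")

        if rng.random() < spec.positive_distractor_rate:
            off = builder.add_sentence(
                "The infant showed normal ", "cognitive development", " overall.")
            distractors.append({"doc_id": doc_id, "start": off,
                                "end": off + len("cognitive development"),
                                "surface": "cognitive development",
                                "kind": "positive_connotation"})
        if rng.random() < spec.stop_distractor_rate:
            off = builder.add_sentence("The ", "hippocampus", " appeared intact.")
            distractors.append({"doc_id": doc_id, "start": off,
                                "end": off + len("hippocampus"),
                                "surface": "hippocampus", "kind": "stop_word"})

        builder.add_sentence(rng.choice(_BACKGROUND))
        documents.append(DocumentRecord(doc_id, builder.text))

    corpus = Corpus(documents, annotations)
    bundle = FixtureBundle(ontology, corpus, word_lists, mentions, distractors)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "ontology.obo").write_text(_ontology_to_obo(ontology), encoding="utf-8")
        write_corpus(corpus, out_dir / "docs", out_dir / "anns")
        word_lists.to_dir(out_dir / "word_lists")
        (out_dir / "ledger.json").write_text(
            json.dumps(bundle.ledger, indent=2), encoding="utf-8")
    return bundle
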