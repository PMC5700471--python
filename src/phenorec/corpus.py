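"""Corpus and ontology I/O.

A gold-standard corpus is a pair of directories: one ``*.txt`` file per
abstract (a single line of text, no title) and one annotation file per
abstract whose lines look like::

    [27::42] HP_0000110 | renal dysplasia

Offsets are 0-based, half-open, counted in Unicode characters.  The ontology
is read from an OBO 1.2 flat file.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "DocumentRecord",
    "AnnotationRecord",
    "Corpus",
    "CorpusDiff",
    "Ontology",
    "AnnotationParseError",
    "normalize_hpo_id",
    "parse_annotation_line",
    "format_annotation_line",
    "read_corpus",
    "write_corpus",
    "diff_corpora",
    "load_ontology",
]


class AnnotationParseError(ValueError):
    """A malformed annotation line; message carries file and line number."""


@dataclass(frozen=True)
class DocumentRecord:
    """One abstract: ``doc_id`` is the file stem (e.g. a PubMed id)."""

    doc_id: str
    text: str


@dataclass(frozen=True)
class AnnotationRecord:
    """One gold or predicted mention: half-open character span plus accession."""

    doc_id: str
    start: int
    end: int
    hpo_id: str
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}::{self.end}] in {self.doc_id}"
            )

    @property
    def span_key(self) -> tuple[str, int, int]:
        return (self.doc_id, self.start, self.end)

    @property
    def full_key(self) -> tuple[str, int, int, str]:
        return (self.doc_id, self.start, self.end, self.hpo_id)


@dataclass
class Corpus:
    documents: list[DocumentRecord] = field(default_factory=list)
    annotations: list[AnnotationRecord] = field(default_factory=list)
    #: span/text mismatches found at load time (doc_id, annotation, actual text)
    mismatches: list[tuple[str, AnnotationRecord, str]] = field(
        default_factory=list, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_id in corpus")
        known = set(ids)
        for ann in self.annotations:
            if ann.doc_id not in known:
                raise ValueError(f"annotation references unknown doc_id {ann.doc_id!r}")

    def text_of(self, doc_id: str) -> str:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d.text
        raise KeyError(doc_id)

    def annotations_for(self, doc_id: str) -> list[AnnotationRecord]:
        return [a for a in self.annotations if a.doc_id == doc_id]

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]


_HPO_ID_RE = re.compile(r"^HP[_:](\d+)$")

# accepts ASCII "|" or the Unicode divider some files use
_ANN_LINE_RE = re.compile(
    r"^\s*\[(\d+)::(\d+)\]\s+(HP[_:]\d+)\s*[|∣]\s?(.*\S)\s*$"
)


def normalize_hpo_id(raw: str) -> str:
    """Canonical accession form: ``HP_`` + 7 digits; accepts ``HP:`` input."""
    m = _HPO_ID_RE.match(raw.strip())
    if not m:
        raise ValueError(f"not an HPO accession: {raw!r}")
    return "HP_" + m.group(1).zfill(7)


def parse_annotation_line(
    line: str, doc_id: str = "", *, source: str = "<string>", lineno: int = 0
) -> AnnotationRecord:
    """Parse one ``[start::end] HP_nnnnnnn | surface`` record."""
    m = _ANN_LINE_RE.match(line)
    if not m:
        raise AnnotationParseError(
            f"{source}:{lineno}: malformed annotation line: {line!r}"
        )
    start, end = int(m.group(1)), int(m.group(2))
    surface = m.group(4)
    if end - start != len(surface):
        # keep the file's offsets; the caller decides whether this is fatal
        warnings.warn(
            f"{source}:{lineno}: span width {end - start} != surface length "
            f"{len(surface)} for {surface!r}",
            stacklevel=2,
        )
    return AnnotationRecord(doc_id, start, end, normalize_hpo_id(m.group(3)), surface)


def format_annotation_line(ann: AnnotationRecord) -> str:
    return f"[{ann.start}::{ann.end}] {ann.hpo_id} | {ann.surface}"


def _read_doc(path: Path) -> str:
    # abstracts are a single block; strip the trailing newline only
    text = path.read_text(encoding="utf-8")
    return text.rstrip("\n")


def read_corpus(doc_dir: str | Path, ann_dir: str | Path, *, strict: bool = False) -> Corpus:
    """Load a corpus from document and annotation directories.

    Every annotation file must have a matching document file (same stem).
    Annotations whose span text does not match the document are recorded in
    ``corpus.mismatches``; with ``strict=True`` they raise instead.
    """
    doc_dir, ann_dir = Path(doc_dir), Path(ann_dir)
    if not doc_dir.is_dir():
        raise FileNotFoundError(f"document directory not found: {doc_dir}")
    if not ann_dir.is_dir():
        raise FileNotFoundError(f"annotation directory not found: {ann_dir}")

    docs: dict[str, DocumentRecord] = {}
    for path in sorted(doc_dir.glob("*.txt")):
        docs[path.stem] = DocumentRecord(path.stem, _read_doc(path))

    orphans = [p.name for p in sorted(ann_dir.iterdir()) if p.is_file() and p.stem not in docs]
    if orphans:
        raise ValueError(f"annotation files without a matching document: {orphans}")

    annotations: list[AnnotationRecord] = []
    mismatches: list[tuple[str, AnnotationRecord, str]] = []
    for path in sorted(ann_dir.iterdir()):
        if not path.is_file():
            continue
        doc = docs[path.stem]
        for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            ann = parse_annotation_line(line, doc.doc_id, source=str(path), lineno=lineno)
            if ann.end > len(doc.text) or doc.text[ann.start : ann.end] != ann.surface:
                actual = doc.text[ann.start : ann.end]
                if strict:
                    raise ValueError(
                        f"{path}:{lineno}: span text {actual!r} != surface {ann.surface!r}"
                    )
                mismatches.append((doc.doc_id, ann, actual))
            annotations.append(ann)

    corpus = Corpus(list(docs.values()), annotations)
    corpus.mismatches = mismatches
    return corpus


def write_corpus(corpus: Corpus, doc_dir: str | Path, ann_dir: str | Path) -> None:
    """Write ``corpus`` in the directory layout ``read_corpus`` consumes."""
    doc_dir, ann_dir = Path(doc_dir), Path(ann_dir)
    doc_dir.mkdir(parents=True, exist_ok=True)
    ann_dir.mkdir(parents=True, exist_ok=True)
    by_doc: dict[str, list[AnnotationRecord]] = {d.doc_id: [] for d in corpus.documents}
    for ann in corpus.annotations:
        by_doc[ann.doc_id].append(ann)
    for doc in corpus.documents:
        (doc_dir / f"{doc.doc_id}.txt").write_text(doc.text + "\n", encoding="utf-8")
        lines = [
            format_annotation_line(a)
            for a in sorted(by_doc[doc.doc_id], key=lambda a: (a.start, a.end, a.hpo_id))
        ]
        (ann_dir / f"{doc.doc_id}.txt").write_text(
            "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
        )


@dataclass
class CorpusDiff:
    added: list[AnnotationRecord]
    removed: list[AnnotationRecord]
    #: pairs (old, new) occupying the same span with different id or surface
    modified: list[tuple[AnnotationRecord, AnnotationRecord]]

    def to_tsv(self) -> str:
        rows = ["doc_id\tstart\tend\thpo_id\tsurface\tstatus"]
        for status, anns in (("added", self.added), ("removed", self.removed)):
            for a in anns:
                rows.append(f"{a.doc_id}\t{a.start}\t{a.end}\t{a.hpo_id}\t{a.surface}\t{status}")
        for old, new in self.modified:
            rows.append(
                f"{new.doc_id}\t{new.start}\t{new.end}\t{new.hpo_id}\t{new.surface}\tmodified"
            )
        return "\n".join(rows) + "\n"


def diff_corpora(old: Corpus, new: Corpus) -> CorpusDiff:
    """Annotation-level diff of two corpora over the same document set.

    Span keys (doc_id, start, end) partition the comparison: spans only in
    ``new`` are added, spans only in ``old`` are removed, shared spans whose
    accession or surface changed are modified.
    """
    old_ids, new_ids = set(old.doc_ids), set(new.doc_ids)
    if old_ids != new_ids:
        raise ValueError(
            f"document sets differ: only-old={sorted(old_ids - new_ids)} "
            f"only-new={sorted(new_ids - old_ids)}"
        )
    old_by_span = {a.span_key: a for a in old.annotations}
    new_by_span = {a.span_key: a for a in new.annotations}
    added = [a for k, a in sorted(new_by_span.items()) if k not in old_by_span]
    removed = [a for k, a in sorted(old_by_span.items()) if k not in new_by_span]
    modified = [
        (old_by_span[k], new_by_span[k])
        for k in sorted(old_by_span.keys() & new_by_span.keys())
        if (old_by_span[k].hpo_id, old_by_span[k].surface)
        != (new_by_span[k].hpo_id, new_by_span[k].surface)
    ]
    return CorpusDiff(added, removed, modified)


# --------------------------------------------------------------------------
# Ontology (OBO 1.2 flat file)
# --------------------------------------------------------------------------

@dataclass
class Ontology:
    """Term names, synonyms and parent links keyed by canonical accession."""

    terms: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, set[str]] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.synonyms:
            if key not in self.terms:
                raise ValueError(f"synonym entry for unknown term {key}")
        for child, ps in self.parents.items():
            if child in ps:
                raise ValueError(f"self-parenting term {child}")

    def surface_forms(self) -> Iterator[tuple[str, str, str]]:
        """Yield (surface, hpo_id, source) over all names and synonyms."""
        for hpo_id, name in self.terms.items():
            yield name, hpo_id, "ontology_name"
        for hpo_id, syns in self.synonyms.items():
            for s in syns:
                yield s, hpo_id, "ontology_synonym"


_SYNONYM_RE = re.compile(r'^"(.*)"')


def load_ontology(obo_path: str | Path) -> Ontology:
    """Parse an OBO 1.2 file into an :class:`Ontology`; obsoletes dropped."""
    path = Path(obo_path)
    if not path.is_file():
        raise FileNotFoundError(f"OBO file not found: {path}")

    terms: dict[str, str] = {}
    synonyms: dict[str, set[str]] = {}
    parents: dict[str, set[str]] = {}

    stanza: dict[str, list[str]] | None = None
    in_term = False
    saw_term_stanza = False

    def flush() -> None:
        if stanza is None or not in_term:
            return
        if stanza.get("is_obsolete", ["false"])[0].strip().lower() == "true":
            return
        ids = stanza.get("id")
        names = stanza.get("name")
        if not ids or not names:
            return
        try:
            hpo_id = normalize_hpo_id(ids[0].strip())
        except ValueError:
            return  # foreign-namespace term
        terms[hpo_id] = names[0].strip()
        syns = set()
        for raw in stanza.get("synonym", []):
            m = _SYNONYM_RE.match(raw.strip())
            if m and m.group(1):
                syns.add(m.group(1))
        if syns:
            synonyms[hpo_id] = syns
        ps = set()
        for raw in stanza.get("is_a", []):
            try:
                ps.add(normalize_hpo_id(raw.split("!")[0].strip()))
            except ValueError:
                pass
        if ps:
            parents[hpo_id] = ps

    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            saw_term_stanza = saw_term_stanza or in_term
            stanza = {}
            continue
        if stanza is None or not line or line.startswith("!"):
            continue
        key, _, value = line.partition(":")
        if not _:
            continue
        stanza.setdefault(key.strip(), []).append(value.strip())
    flush()

    if not saw_term_stanza:
        raise ValueError(f"no [Term] stanzas found in {path}; not an OBO file?")
    return Ontology(terms, synonyms, parents)
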