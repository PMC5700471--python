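"""Validation dictionary and rule word-lists.

The dictionary maps normalized surface forms to ontology accessions and is
assembled from three sources: ontology names/synonyms, training-set
annotation surfaces (never the held-out test fold), and generated term
variations such as ``abnormalities of the kidney`` ↔ ``kidney
abnormalities``.  The word lists (common phenotype head nouns, connector
phrases, positive-connotation nouns and two stop lists) are configuration
shipped as editable text files, one phrase per line, ``#`` comments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from phenorec.corpus import AnnotationRecord, Ontology

__all__ = [
    "Dictionary",
    "WordLists",
    "DictionaryMatch",
    "normalize_surface",
    "build_dictionary",
    "generate_variations",
    "find_dictionary_mentions",
    "singular_plural_variants",
]


def normalize_surface(surface: str) -> str:
    """Lower-case and collapse internal whitespace (idempotent)."""
    return " ".join(surface.lower().split())


def _read_word_list(text: str) -> list[str]:
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(normalize_surface(line))
    return out


def _load_packaged(name: str) -> list[str]:
    ref = resources.files("phenorec").joinpath("data", name)
    return _read_word_list(ref.read_text(encoding="utf-8"))


@dataclass
class WordLists:
    common_hpo_nouns: list[str] = field(default_factory=list)
    connector_phrases: list[str] = field(default_factory=list)
    positive_connotation_nouns: list[str] = field(default_factory=list)
    stop_exact: list[str] = field(default_factory=list)
    stop_partial: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("stop_exact", "stop_partial"):
            setattr(self, name, [normalize_surface(p) for p in getattr(self, name)])

    @classmethod
    def default(cls) -> "WordLists":
        """Lists bundled with the package."""
        return cls(
            common_hpo_nouns=_load_packaged("common_hpo_nouns.txt"),
            connector_phrases=_load_packaged("connector_phrases.txt"),
            positive_connotation_nouns=_load_packaged("positive_connotation_nouns.txt"),
            stop_exact=_load_packaged("stop_exact.txt"),
            stop_partial=_load_packaged("stop_partial.txt"),
        )

    @classmethod
    def from_dir(cls, directory: str | Path) -> "WordLists":
        directory = Path(directory)

        def load(name: str) -> list[str]:
            path = directory / f"{name}.txt"
            return _read_word_list(path.read_text(encoding="utf-8")) if path.is_file() else []

        return cls(
            common_hpo_nouns=load("common_hpo_nouns"),
            connector_phrases=load("connector_phrases"),
            positive_connotation_nouns=load("positive_connotation_nouns"),
            stop_exact=load("stop_exact"),
            stop_partial=load("stop_partial"),
        )

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("common_hpo_nouns", "connector_phrases",
                     "positive_connotation_nouns", "stop_exact", "stop_partial"):
            lines = getattr(self, name)
            (directory / f"{name}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
            )


@dataclass
class Dictionary:
    """Normalized surface form → ontology accessions, with provenance."""

    entries: dict[str, set[str]] = field(default_factory=dict)
    sources: dict[str, set[str]] = field(default_factory=dict)

    def add(self, surface: str, hpo_ids: Iterable[str], source: str) -> None:
        key = normalize_surface(surface)
        if not key:
            return
        self.entries.setdefault(key, set()).update(hpo_ids)
        self.sources.setdefault(key, set()).add(source)

    def __contains__(self, surface: str) -> bool:
        return normalize_surface(surface) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, surface: str) -> set[str]:
        return set(self.entries.get(normalize_surface(surface), set()))

    def to_tsv(self) -> str:
        rows = ["surface\thpo_id\tsource"]
        for surface in sorted(self.entries):
            ids = sorted(self.entries[surface]) or [""]
            srcs = ",".join(sorted(self.sources.get(surface, set())))
            for hid in ids:
                rows.append(f"{surface}\t{hid}\t{srcs}")
        return "\n".join(rows) + "\n"


def singular_plural_variants(noun: str) -> set[str]:
    """Inflection pair for a head noun: {abnormality, abnormalities}."""
    out = {noun}
    if noun.endswith("ies"):
        out.add(noun[:-3] + "y")
    elif noun.endswith("y"):
        out.add(noun[:-1] + "ies")
    elif noun.endswith(("ss", "x", "ch", "sh")):
        out.add(noun + "es")
    elif noun.endswith("s"):
        out.add(noun[:-1])
    else:
        out.add(noun + "s")
    return out


def generate_variations(
    term: str,
    connector_phrases: Iterable[str],
    common_hpo_nouns: Iterable[str] = (),
) -> set[str]:
    """Surface rewrites of one term; the original is always included.

    ``<head> <connector> <tail>`` → ``<tail> <head>`` (e.g. "abnormalities of
    the kidney" → "kidney abnormalities"), and the reverse direction for
    two-word ``<mod> <head>`` terms whose head is a common phenotype noun
    ("kidney abnormalities" → "abnormalities of the kidney").
    """
    term = normalize_surface(term)
    out = {term}
    if not term:
        return set()
    connectors = sorted({normalize_surface(c) for c in connector_phrases},
                        key=len, reverse=True)
    common = {normalize_surface(n) for n in common_hpo_nouns}

    for conn in connectors:
        marker = f" {conn} "
        if marker in term:
            head, tail = term.split(marker, 1)
            if head and tail:
                out.add(f"{tail} {head}")
                break  # longest connector wins

    words = term.split()
    if len(words) == 2 and words[1] in common:
        mod, head = words
        out.add(f"{head} of the {mod}")

    # inflection variants for common head nouns only
    for i, w in enumerate(words):
        if w in common:
            for variant in singular_plural_variants(w):
                if variant != w:
                    out.add(" ".join(words[:i] + [variant] + words[i + 1 :]))
    return out


def build_dictionary(
    ontology: Ontology,
    training_annotations: Iterable[AnnotationRecord] = (),
    generate: bool = True,
    word_lists: WordLists | None = None,
) -> Dictionary:
    """Assemble the validation dictionary.

    Callers are responsible for passing only *training* annotations so the
    held-out test fold never leaks into the rules.
    """
    wl = word_lists or WordLists.default()
    d = Dictionary()
    base: list[tuple[str, set[str], str]] = []
    for surface, hpo_id, source in ontology.surface_forms():
        base.append((surface, {hpo_id}, source))
    for ann in training_annotations:
        base.append((ann.surface, {ann.hpo_id}, "training_annotation"))

    for surface, ids, source in base:
        d.add(surface, ids, source)
        if generate:
            for var in generate_variations(surface, wl.connector_phrases, wl.common_hpo_nouns):
                if normalize_surface(var) != normalize_surface(surface):
                    d.add(var, ids, "generated_variation")
    return d


@dataclass(frozen=True)
class DictionaryMatch:
    start: int
    end: int
    surface: str
    hpo_ids: frozenset[str]


def _entry_pattern(entry: str) -> re.Pattern:
    words = [re.escape(w) for w in entry.split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(words) + r"(?!\w)", re.IGNORECASE)


def find_dictionary_mentions(doc_text: str, dictionary: Dictionary) -> list[DictionaryMatch]:
    """All case-insensitive exact matches of dictionary entries.

    Matches respect word boundaries; each entry matches greedily left to
    right (longest-match-wins within one entry), while *distinct* entries may
    overlap or nest — superclass and subclass mentions are both reported.
    """
    matches: list[DictionaryMatch] = []
    for entry in dictionary.entries:
        for m in _entry_pattern(entry).finditer(doc_text):
            matches.append(
                DictionaryMatch(
                    m.start(), m.end(), doc_text[m.start() : m.end()],
                    frozenset(dictionary.entries[entry]),
                )
            )
    matches.sort(key=lambda x: (x.start, -(x.end - x.start)))
    return matches
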