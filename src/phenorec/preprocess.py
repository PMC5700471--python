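"""Offset-preserving text preprocessing.

The downstream rules depend only on tag *classes* (noun / adjective /
preposition / determiner), so the tagging backend is a contract: Penn
Treebank tags, lemmas, and exact character offsets into the source document.
One lightweight rule-based backend is bundled; a heavier tagger can be
plugged in by registering a callable with the same signature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable

__all__ = [
    "Token",
    "Sentence",
    "split_sentences",
    "tokenize_and_tag",
    "preprocess_document",
    "penn_tag",
    "lemmatize",
]


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int
    pos: str = ""
    lemma: str = ""


@dataclass
class Sentence:
    doc_id: str
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)

    def text(self, doc_text: str) -> str:
        return doc_text[self.start : self.end]


# --------------------------------------------------------------------------
# Sentence splitting
# --------------------------------------------------------------------------

# abbreviations that should not terminate a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "cf", "al", "etc", "vs", "ca", "approx", "fig", "figs",
    "dr", "mr", "mrs", "ms", "prof", "no", "vol", "st",
}

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s+\S|\s*$)")


def _is_abbreviation(text: str, dot_idx: int) -> bool:
    m = re.search(r"(\w[\w.]*)$", text[:dot_idx])
    if not m:
        return False
    word = m.group(1).rstrip(".").lower()
    if word in _ABBREVIATIONS or word.rstrip(".") in _ABBREVIATIONS:
        return True
    # single letters ("J. Smith") and dotted acronyms ("U.S.")
    return len(word.replace(".", "")) == 1 or "." in word


def split_sentences(doc) -> list[Sentence]:
    """Split a document into sentences with exact character spans.

    Spans cover the non-whitespace extent of each sentence; the text between
    consecutive spans is whitespace only, so joining the slices with the gaps
    reconstructs the document.
    """
    text = doc.text
    boundaries: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        if _is_abbreviation(text, m.start()):
            # ".!?" runs after an abbreviation still end a sentence when the
            # next word is capitalized and the abbreviation is sentence-final
            # ("… et al. The study …") — keep it simple: never split here.
            continue
        boundaries.append(m.end())
    if not boundaries or boundaries[-1] < len(text):
        boundaries.append(len(text))

    sentences: list[Sentence] = []
    cursor = 0
    for b in boundaries:
        chunk = text[cursor:b]
        stripped = chunk.strip()
        if stripped:
            start = cursor + (len(chunk) - len(chunk.lstrip()))
            sentences.append(Sentence(doc.doc_id, start, start + len(stripped)))
        cursor = b
    return sentences


# --------------------------------------------------------------------------
# Tokenization
# --------------------------------------------------------------------------

# words keep internal hyphens and apostrophes (phenotype terms are hyphen-rich)
_TOKEN_RE = re.compile(r"\w+(?:['’-]\w+)*|\S")


def _tokenize(text: str, offset: int) -> list[Token]:
    return [
        Token(m.group(0), offset + m.start(), offset + m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


# --------------------------------------------------------------------------
# POS tagging (rule-based Penn tagger)
# --------------------------------------------------------------------------

_CLOSED_CLASS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "each": "DT", "every": "DT", "some": "DT",
    "any": "DT", "all": "DT", "both": "DT", "no": "DT",
    "of": "IN", "in": "IN", "on": "IN", "with": "IN", "without": "IN",
    "for": "IN", "at": "IN", "by": "IN", "from": "IN", "into": "IN",
    "during": "IN", "after": "IN", "before": "IN", "between": "IN",
    "among": "IN", "within": "IN", "under": "IN", "over": "IN",
    "through": "IN", "as": "IN", "upon": "IN", "since": "IN",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "to": "TO",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "has": "VBZ", "have": "VBP", "had": "VBD",
    "do": "VBP", "does": "VBZ", "did": "VBD",
    "can": "MD", "could": "MD", "may": "MD", "might": "MD", "must": "MD",
    "shall": "MD", "should": "MD", "will": "MD", "would": "MD",
    "he": "PRP", "she": "PRP", "it": "PRP", "they": "PRP", "we": "PRP",
    "i": "PRP", "you": "PRP",
    "his": "PRP$", "her": "PRP$", "its": "PRP$", "their": "PRP$", "our": "PRP$",
    "not": "RB", "also": "RB", "very": "RB", "only": "RB",
    "who": "WP", "which": "WDT", "when": "WRB", "where": "WRB",
    "there": "EX",
}

# irregular plural → singular (covers the fixture/biomedical vocabulary)
_IRREGULAR_NOUNS = {
    "feet": "foot", "teeth": "tooth", "men": "man", "women": "woman",
    "children": "child", "vertebrae": "vertebra", "foramina": "foramen",
    "ganglia": "ganglion", "nuclei": "nucleus", "diagnoses": "diagnosis",
    "analyses": "analysis", "stenoses": "stenosis", "scolioses": "scoliosis",
}

# frequent adjectives the suffix rules miss
_ADJ_LEXICON = {
    "severe", "mild", "acute", "chronic", "normal", "abnormal", "outer",
    "inner", "middle", "upper", "lower", "left", "right", "large", "small",
    "broad", "narrow", "short", "long", "deep", "coarse", "sparse", "enlarged",
}

_ADJ_SUFFIXES = (
    "al", "ar", "ic", "ous", "ive", "ary", "able", "ible", "ile", "oid",
    "ent", "ant", "less", "ful",
)

_PUNCT_TAGS = {",": ",", ".": ".", ";": ":", ":": ":", "(": "-LRB-", ")": "-RRB-",
               "?": ".", "!": ".", '"': "''", "'": "''", "%": "NN"}


def penn_tag(word: str, is_sentence_initial: bool = False) -> str:
    """Assign a Penn Treebank tag to a single word, context-free."""
    lower = word.lower()
    if not word[0].isalnum() and len(word) == 1:
        return _PUNCT_TAGS.get(word, "SYM")
    if re.fullmatch(r"[\d.,/-]*\d[\d.,/-]*", word):
        return "CD"
    if lower in _CLOSED_CLASS:
        return _CLOSED_CLASS[lower]
    if lower in _ADJ_LEXICON:
        return "JJ"
    if lower.endswith("ly") and len(lower) > 3:
        return "RB"
    if lower.endswith("ing") and len(lower) > 4:
        return "VBG"
    if lower.endswith("ed") and len(lower) > 3:
        return "VBN"
    if lower in _IRREGULAR_NOUNS:
        return "NNS"
    for suf in _ADJ_SUFFIXES:
        if lower.endswith(suf) and len(lower) > len(suf) + 1:
            return "JJ"
    if lower.endswith("s") and not lower.endswith(("ss", "us", "is")) and len(lower) > 3:
        return "NNS"
    if word[0].isupper() and not is_sentence_initial:
        return "NNP"
    return "NN"


# --------------------------------------------------------------------------
# Lemmatization
# --------------------------------------------------------------------------

def lemmatize(word: str, pos: str) -> str:
    lower = word.lower()
    if pos == "NNS":
        if lower in _IRREGULAR_NOUNS:
            return _IRREGULAR_NOUNS[lower]
        if lower.endswith("ies") and len(lower) > 4:
            return lower[:-3] + "y"
        if lower.endswith(("ches", "shes", "sses", "xes", "zes")):
            return lower[:-2]
        if lower.endswith("s") and not lower.endswith("ss"):
            return lower[:-1]
    elif pos == "VBG" and lower.endswith("ing") and len(lower) > 4:
        stem = lower[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2]:  # running → run
            return stem[:-1]
        return stem
    elif pos in ("VBD", "VBN") and lower.endswith("ed") and len(lower) > 3:
        stem = lower[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2]:
            return stem[:-1]
        if stem.endswith(("at", "iz", "os", "in", "ur", "uc")):  # heuristic -e
            return stem + "e"
        return stem
    return lower


# --------------------------------------------------------------------------
# Backend registry
# --------------------------------------------------------------------------

TaggerBackend = Callable[[Sentence, str], Sentence]


def _builtin_backend(sentence: Sentence, doc_text: str) -> Sentence:
    tokens = _tokenize(doc_text[sentence.start : sentence.end], sentence.start)
    tagged = []
    for i, tok in enumerate(tokens):
        pos = penn_tag(tok.text, is_sentence_initial=(i == 0))
        tagged.append(replace(tok, pos=pos, lemma=lemmatize(tok.text, pos)))
    return Sentence(sentence.doc_id, sentence.start, sentence.end, tagged)


_BACKENDS: dict[str, TaggerBackend] = {"builtin": _builtin_backend}


def register_backend(name: str, backend: TaggerBackend) -> None:
    _BACKENDS[name] = backend


def tokenize_and_tag(sentence: Sentence, doc_text: str, backend: str = "builtin") -> Sentence:
    """Fill a sentence with offset-true, tagged and lemmatized tokens."""
    out = _BACKENDS[backend](sentence, doc_text)
    for tok in out.tokens:
        assert doc_text[tok.start : tok.end] == tok.text, "backend broke offsets"
        assert tok.pos and tok.lemma, "backend must tag and lemmatize"
    return out


def preprocess_document(doc, backend: str = "builtin") -> list[Sentence]:
    """Sentence-split, tokenize, tag and lemmatize one document."""
    return [tokenize_and_tag(s, doc.text, backend) for s in split_sentences(doc)]
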