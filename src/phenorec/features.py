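"""Token feature extraction and BIO label projection.

Six feature families feed the sequence labeler:

* linguistic — lemma and POS of the current token;
* orthographic — word case and per-symbol presence flags;
* morphological — prefixes (len 2–3), suffixes (len 1–4), word shape,
  character bigrams;
* context — lemma (±2), POS (±4), shape (±2), and affixes (±1) of
  neighbouring tokens, each feature stamped with its offset;
* lexical — stop-word flags in a ±4 window;
* other — Brown-cluster path (full + 4/6-bit prefixes) and a word-length
  class.

The current token's text (``w=``) is always emitted: with every family
disabled the extractor reduces to that bare baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from phenorec.brown import BrownClusters
from phenorec.corpus import AnnotationRecord
from phenorec.preprocess import Sentence

__all__ = [
    "FeatureConfig",
    "LabeledSequence",
    "word_shape",
    "token_features",
    "sentence_features",
    "encode_bio",
    "decode_bio",
    "DEFAULT_STOP_WORDS",
]

BOS = "__BOS__"
EOS = "__EOS__"

#: small function-word list backing the lexical (stop word) family
DEFAULT_STOP_WORDS = frozenset(
    """a an and are as at be been by for from has have in is it its of on or
    that the these this to was were which with within without""".split()
)


@dataclass
class FeatureConfig:
    """Switches and window sizes for the six feature families."""

    linguistic: bool = True
    orthographic: bool = True
    morphological: bool = True
    context: bool = True
    lexical: bool = True
    other: bool = True

    prefix_lengths_current: tuple[int, ...] = (2, 3)
    suffix_lengths_current: tuple[int, ...] = (1, 2, 3, 4)
    lemma_window: int = 2
    pos_window: int = 4
    shape_window: int = 2
    affix_window: int = 1
    # "length from 1 and 4" read as the two lengths {1, 4}, mirroring the
    # current-token phrasing "from 2 and 3" = {2, 3}; override for {1..4}
    context_prefix_lengths: tuple[int, ...] = (1, 4)
    context_suffix_lengths: tuple[int, ...] = (1, 4)
    stopword_window: int = 4
    length_class_bins: tuple[int, ...] = (1, 3, 6, 10)

    def __post_init__(self) -> None:
        for w in (self.lemma_window, self.pos_window, self.shape_window,
                  self.affix_window, self.stopword_window):
            if w < 0:
                raise ValueError("window sizes must be >= 0")
        bins = self.length_class_bins
        if any(b >= c for b, c in zip(bins, bins[1:])):
            raise ValueError("length_class_bins must be strictly increasing")

    @classmethod
    def baseline(cls) -> "FeatureConfig":
        return cls(linguistic=False, orthographic=False, morphological=False,
                   context=False, lexical=False, other=False)


@dataclass
class LabeledSequence:
    """CRF input: parallel tokens, BIO labels and per-token feature lists."""

    sentence: Sentence
    labels: list[str]
    features: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sentence.tokens):
            raise ValueError("labels and tokens must align")
        prev = "O"
        for lab in self.labels:
            if lab not in ("B", "I", "O"):
                raise ValueError(f"bad label {lab!r}")
            if lab == "I" and prev == "O":
                raise ValueError("I may not follow O")
            prev = lab


def word_shape(text: str, collapse: bool = False) -> str:
    """Map letters/digits to class symbols: ``Kidney`` → ``Xxxxxx``.

    Uppercase → X, lowercase → x, digit → d; everything else verbatim.  With
    ``collapse=True`` runs of the same symbol are squeezed (``Xx``).
    """
    out = []
    for ch in text:
        if ch.isupper():
            out.append("X")
        elif ch.islower():
            out.append("x")
        elif ch.isdigit():
            out.append("d")
        else:
            out.append(ch)
    shape = "".join(out)
    if collapse:
        squeezed = [shape[0]] if shape else []
        for ch in shape[1:]:
            if ch != squeezed[-1]:
                squeezed.append(ch)
        shape = "".join(squeezed)
    return shape


_SYMBOL_FLAGS = [
    ("digit", str.isdigit),
    ("lbracket", "[".__eq__),
    ("rbracket", "]".__eq__),
    ("slash", "/".__eq__),
    ("dash", "-".__eq__),
    ("quote", "'".__eq__),
    ("dquote", '"'.__eq__),
    ("lparen", "(".__eq__),
    ("rparen", ")".__eq__),
]


def _word_case(text: str) -> str:
    if text.isupper():
        return "upper"
    if text.islower():
        return "lower"
    if text[:1].isupper() and text[1:].islower():
        return "title"
    return "mixed"


def _length_class(n: int, bins: tuple[int, ...]) -> str:
    lo = 1
    for b in bins:
        if n <= b:
            return f"{lo}-{b}" if lo != b else str(b)
        lo = b + 1
    return f"{lo}+"


def _ctx(sentence: Sentence, i: int, off: int, attr: str) -> str:
    j = i + off
    if j < 0:
        return BOS
    if j >= len(sentence.tokens):
        return EOS
    tok = sentence.tokens[j]
    if attr == "shape":
        return word_shape(tok.text)
    return getattr(tok, attr)


def _window_offsets(w: int) -> list[int]:
    return [off for off in range(-w, w + 1) if off != 0]


def token_features(
    sentence: Sentence,
    index: int,
    config: FeatureConfig,
    stop_words: frozenset[str] = DEFAULT_STOP_WORDS,
    brown: BrownClusters | None = None,
) -> list[str]:
    """Feature strings (``name=value``) for one token."""
    tok = sentence.tokens[index]
    text = tok.text
    feats = [f"w={text}"]

    if config.linguistic:
        feats.append(f"lemma={tok.lemma}")
        feats.append(f"pos={tok.pos}")

    if config.orthographic:
        feats.append(f"case={_word_case(text)}")
        for name, pred in _SYMBOL_FLAGS:
            if any(pred(ch) for ch in text):
                feats.append(f"has_{name}=1")

    if config.morphological:
        for n in config.prefix_lengths_current:
            if len(text) >= n:
                feats.append(f"prefix{n}={text[:n]}")
        for n in config.suffix_lengths_current:
            if len(text) >= n:
                feats.append(f"suffix{n}={text[-n:]}")
        feats.append(f"shape={word_shape(text)}")
        feats.append(f"shapec={word_shape(text, collapse=True)}")
        for a, b in zip(text, text[1:]):
            feats.append(f"bigram={a}{b}")

    if config.context:
        for off in _window_offsets(config.lemma_window):
            feats.append(f"lemma[{off:+d}]={_ctx(sentence, index, off, 'lemma')}")
        for off in _window_offsets(config.pos_window):
            feats.append(f"pos[{off:+d}]={_ctx(sentence, index, off, 'pos')}")
        for off in _window_offsets(config.shape_window):
            feats.append(f"shape[{off:+d}]={_ctx(sentence, index, off, 'shape')}")
        for off in _window_offsets(config.affix_window):
            ctx_text = _ctx(sentence, index, off, "text")
            for n in config.context_prefix_lengths:
                if ctx_text not in (BOS, EOS) and len(ctx_text) >= n:
                    feats.append(f"prefix{n}[{off:+d}]={ctx_text[:n]}")
            for n in config.context_suffix_lengths:
                if ctx_text not in (BOS, EOS) and len(ctx_text) >= n:
                    feats.append(f"suffix{n}[{off:+d}]={ctx_text[-n:]}")

    if config.lexical:
        for off in [0, *_window_offsets(config.stopword_window)]:
            word = _ctx(sentence, index, off, "text")
            flag = "1" if word.lower() in stop_words else "0"
            feats.append(f"stop[{off:+d}]={flag}")

    if config.other:
        path = brown.path(text) if brown is not None else ""
        if path:
            feats.append(f"brown={path}")
            feats.append(f"brown4={path[:4]}")
            feats.append(f"brown6={path[:6]}")
        feats.append(f"lenclass={_length_class(len(text), config.length_class_bins)}")

    return feats


def sentence_features(
    sentence: Sentence,
    config: FeatureConfig,
    stop_words: frozenset[str] = DEFAULT_STOP_WORDS,
    brown: BrownClusters | None = None,
) -> list[list[str]]:
    return [
        token_features(sentence, i, config, stop_words, brown)
        for i in range(len(sentence.tokens))
    ]


# --------------------------------------------------------------------------
# BIO projection
# --------------------------------------------------------------------------

def _select_non_overlapping(annotations: list[AnnotationRecord]) -> list[AnnotationRecord]:
    """Longest-span-wins selection of non-overlapping gold spans."""
    chosen: list[AnnotationRecord] = []
    for ann in sorted(annotations, key=lambda a: (-(a.end - a.start), a.start)):
        if all(ann.end <= c.start or ann.start >= c.end for c in chosen):
            chosen.append(ann)
    return sorted(chosen, key=lambda a: a.start)


def encode_bio(sentence: Sentence, annotations: list[AnnotationRecord]) -> LabeledSequence:
    """Project gold spans onto token labels (B first token, I the rest).

    Overlapping gold spans are resolved longest-first; spans that cross token
    boundaries extend to the covering tokens (recall-preserving).
    """
    relevant = [
        a for a in annotations if a.start < sentence.end and a.end > sentence.start
    ]
    labels = ["O"] * len(sentence.tokens)
    for ann in _select_non_overlapping(relevant):
        first = True
        for i, tok in enumerate(sentence.tokens):
            if tok.start < ann.end and tok.end > ann.start:
                labels[i] = "B" if first else "I"
                first = False
    return LabeledSequence(sentence, labels)


def repair_bio(labels: list[str]) -> list[str]:
    """Turn stray ``I`` after ``O`` (or at start) into ``B``."""
    out = list(labels)
    prev = "O"
    for i, lab in enumerate(out):
        if lab == "I" and prev == "O":
            out[i] = "B"
        prev = out[i]
    return out


def decode_bio(seq: LabeledSequence, doc_text: str) -> list[tuple[int, int, str]]:
    """Maximal ``B I*`` runs → (start, end, surface) document spans."""
    labels = repair_bio(seq.labels)
    spans: list[tuple[int, int, str]] = []
    tokens = seq.sentence.tokens
    i = 0
    while i < len(labels):
        if labels[i] == "B":
            j = i + 1
            while j < len(labels) and labels[j] == "I":
                j += 1
            start, end = tokens[i].start, tokens[j - 1].end
            spans.append((start, end, doc_text[start:end]))
            i = j
        else:
            i += 1
    return spans
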