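"""Dictionary-plus-rules validation of sequence-labeler output.

Two rule phases run in a fixed order.  Identification rules only ever add
candidate entities (dictionary mentions, head-noun structures, boundary
expansion across coordination, splitting of coordinated tails, and a single
second pass over the enlarged entity list).  Removal rules only ever
deactivate candidates, each recording its reason for the audit trail
(obvious formal errors, bad final tokens, positive-connotation two-token
candidates, and two stop lists with exact and partial matching).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from phenorec.lexicon import Dictionary, WordLists, find_dictionary_mentions, normalize_surface
from phenorec.preprocess import Sentence, Token, penn_tag

__all__ = [
    "CandidateEntity",
    "RuleConfig",
    "rule_entity_variations",
    "rule_longer_entities",
    "rule_smaller_entities",
    "rule_second_validation",
    "rule_general_errors",
    "rule_incorrect_structure",
    "rule_negative_connotation",
    "rule_stop_words",
    "validate",
]

_NOUNISH = {"NN", "NNS", "NNP", "NNPS"}
_MODIFIER = {"JJ", "VBG", "VBN"} | _NOUNISH


@dataclass
class CandidateEntity:
    doc_id: str
    start: int
    end: int
    surface: str
    origin: str  # crf | dictionary | variation | expansion | split | second_pass
    hpo_ids: frozenset[str] = frozenset()
    status: str = "active"
    removal_reason: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def removed(self, reason: str) -> "CandidateEntity":
        return replace(self, status="removed", removal_reason=reason)


@dataclass
class RuleConfig:
    """On/off switches for every rule, supporting the ablation modes."""

    dictionary: bool = True
    entity_variations: bool = True
    longer_entities: bool = True
    smaller_entities: bool = True
    second_validation: bool = True
    general_errors: bool = True
    incorrect_structure: bool = True
    negative_connotation: bool = True
    stop_words: bool = True
    #: also emit distributed split forms ("A of the C" from "A of the B and C")
    split_distribute: bool = False
    #: correction phase: strip leading digit tokens ("36 schwannomas" →
    #: "schwannomas"); replaces the original candidate, so it belongs to
    #: neither pure phase and only runs in the full configuration
    boundary_trim: bool = True

    @classmethod
    def none(cls) -> "RuleConfig":
        return cls(**{f: False for f in (
            "dictionary", "entity_variations", "longer_entities", "smaller_entities",
            "second_validation", "general_errors", "incorrect_structure",
            "negative_connotation", "stop_words", "boundary_trim")})

    @classmethod
    def identification_only(cls) -> "RuleConfig":
        cfg = cls.none()
        cfg.dictionary = cfg.entity_variations = cfg.longer_entities = True
        cfg.smaller_entities = cfg.second_validation = True
        return cfg

    @classmethod
    def removal_only(cls) -> "RuleConfig":
        cfg = cls.none()
        cfg.general_errors = cfg.incorrect_structure = True
        cfg.negative_connotation = cfg.stop_words = True
        return cfg


# --------------------------------------------------------------------------
# identification rules
# --------------------------------------------------------------------------

def _match_connector(tokens: list[Token], i: int, connectors: list[list[str]]) -> int:
    """Length (in tokens) of the longest connector starting at i, or 0."""
    best = 0
    for conn in connectors:
        n = len(conn)
        if len(tokens) - i >= n and [t.text.lower() for t in tokens[i : i + n]] == conn:
            best = max(best, n)
    return best


def _phrase_end(tokens: list[Token], i: int) -> int | None:
    """Longest run of modifier/coordination tokens from i, trimmed to end on
    a noun; returns the exclusive token index or None."""
    j = i
    while j < len(tokens) and (
        tokens[j].pos in _MODIFIER
        or tokens[j].text.lower() in ("and", "or")
        or tokens[j].text == ","
    ):
        j += 1
    while j > i and tokens[j - 1].pos not in _NOUNISH:
        j -= 1
    return j if j > i else None


def rule_entity_variations(
    sentence: Sentence, doc_text: str, word_lists: WordLists
) -> list[CandidateEntity]:
    """Head-noun structures: ``<common noun> <connector> <noun phrase>``."""
    common = {normalize_surface(n) for n in word_lists.common_hpo_nouns}
    connectors = sorted(
        (c.split() for c in word_lists.connector_phrases), key=len, reverse=True
    )
    tokens = sentence.tokens
    out = []
    for i, tok in enumerate(tokens):
        if tok.text.lower() not in common:
            continue
        n = _match_connector(tokens, i + 1, connectors)
        if not n:
            continue
        end_idx = _phrase_end(tokens, i + 1 + n)
        if end_idx is None:
            continue
        start, end = tok.start, tokens[end_idx - 1].end
        out.append(
            CandidateEntity(sentence.doc_id, start, end, doc_text[start:end], "variation")
        )
    return out


def _token_range(sentence: Sentence, start: int, end: int) -> tuple[int, int] | None:
    """Indices of tokens covered by a document span, or None if disjoint."""
    idx = [i for i, t in enumerate(sentence.tokens) if t.start < end and t.end > start]
    return (idx[0], idx[-1] + 1) if idx else None


def rule_longer_entities(
    sentence: Sentence,
    doc_text: str,
    candidates: list[CandidateEntity],
    dictionary: Dictionary,
    word_lists: WordLists,
) -> list[CandidateEntity]:
    """Expand candidate boundaries across coordination, in both directions.

    From a seeded "rib anomalies" inside "spine and rib anomalies" the
    coordinated modifier "spine and" is absorbed; symmetric expansion onto a
    trailing coordination is also attempted.
    """
    tokens = sentence.tokens
    out = []
    for cand in candidates:
        if cand.status != "active":
            continue
        rng = _token_range(sentence, cand.start, cand.end)
        if rng is None:
            continue
        first, last = rng

        # leftward: absorb noun conjuncts before the span — [noun+ (","
        # noun+)* ("and"|",")] — so adjectives and verbs stop the expansion
        j = first - 1
        took_cc = False
        while j >= 0:
            t = tokens[j]
            if not took_cc:
                if t.text.lower() in ("and", "or") or t.text == ",":
                    took_cc = True
                    j -= 1
                else:
                    break
            else:
                if t.pos in _NOUNISH:
                    j -= 1
                elif t.text == "," and j > 0 and tokens[j - 1].pos in _NOUNISH:
                    j -= 1
                else:
                    break
        left = j + 1
        if took_cc and left < first and tokens[left].pos in _NOUNISH:
            start, end = tokens[left].start, cand.end
            out.append(CandidateEntity(
                cand.doc_id, start, end, doc_text[start:end], "expansion"))

        # rightward: ("and"|",") mod+ ending on a noun, after the span
        j = last
        if j < len(tokens) and (tokens[j].text.lower() in ("and", "or") or tokens[j].text == ","):
            end_idx = _phrase_end(tokens, j + 1)
            if end_idx is not None:
                start, end = cand.start, tokens[end_idx - 1].end
                out.append(CandidateEntity(
                    cand.doc_id, start, end, doc_text[start:end], "expansion"))
    return out


_COORD_SPLIT_RE = re.compile(r"\s*(?:,\s*(?:and|or)\s+|,\s+|\s+(?:and|or)\s+)")


def rule_smaller_entities(
    candidates: list[CandidateEntity],
    word_lists: WordLists,
    distribute: bool = False,
) -> list[CandidateEntity]:
    """Split coordinated tails into component entities; parents retained.

    "pits of the palms and soles" yields the contiguous prefix entity
    "pits of the palms".  With ``distribute=True`` reconstructed forms such
    as "pits of the soles" are also emitted; these carry the span of their
    own conjunct, with the surface rebuilt from the head phrase.
    """
    connectors = sorted(word_lists.connector_phrases, key=len, reverse=True)
    out = []
    for cand in candidates:
        if cand.status != "active":
            continue
        lowered = cand.surface.lower()
        head = conn = tail = None
        for c in connectors:
            m = re.search(rf"\s{re.escape(c)}\s", lowered)
            if m:
                head = cand.surface[: m.start()]
                conn = cand.surface[m.start() : m.end()].strip()
                tail = cand.surface[m.end() :]
                tail_off = cand.start + m.end()
                break
        if tail is None:
            # coordinated modifier form: "<X> and <Y> <noun>" → "<Y> <noun>"
            m = re.search(r"\s+(?:and|or)\s+", lowered)
            if m and " " in cand.surface[m.end():].strip():
                sub_start = cand.start + m.end()
                sub = cand.surface[m.end():]
                out.append(CandidateEntity(
                    cand.doc_id, sub_start, cand.end, sub, "split"))
            continue
        parts = _COORD_SPLIT_RE.split(tail)
        if len(parts) < 2 or not all(p.strip() for p in parts):
            continue
        # contiguous prefix: head + connector + first conjunct
        first_end = cand.start + len(cand.surface) - len(tail) + len(parts[0])
        out.append(CandidateEntity(
            cand.doc_id, cand.start, first_end,
            cand.surface[: first_end - cand.start], "split"))
        if distribute:
            offset = 0
            spans = []
            for p in parts:
                at = tail.find(p, offset)
                spans.append((at, at + len(p)))
                offset = at + len(p)
            for (s, e), part in zip(spans[1:], parts[1:]):
                out.append(CandidateEntity(
                    cand.doc_id, tail_off + s, tail_off + e,
                    f"{head} {conn} {part}", "split"))
    return out


def rule_second_validation(
    sentences: list[Sentence],
    doc_text: str,
    candidates: list[CandidateEntity],
    dictionary: Dictionary,
    word_lists: WordLists,
    config: "RuleConfig",
) -> list[CandidateEntity]:
    """Re-run the identification rules once over the enlarged entity list.

    The entities identified so far act as additional dictionary entries
    (with generated variations), so a mention recognised in one sentence can
    recover its other occurrences — and rewritten forms — document-wide.
    """
    from phenorec.lexicon import generate_variations

    new: list[CandidateEntity] = []
    known = {c.span for c in candidates}

    def take(cands: list[CandidateEntity]) -> None:
        for c in cands:
            if c.span not in known:
                known.add(c.span)
                new.append(replace(c, origin="second_pass"))

    if config.dictionary or config.entity_variations:
        augmented = Dictionary()
        for c in candidates:
            if c.status != "active":
                continue
            for var in generate_variations(
                c.surface, word_lists.connector_phrases, word_lists.common_hpo_nouns
            ):
                augmented.add(var, c.hpo_ids, "second_pass")
        doc_id = sentences[0].doc_id if sentences else ""
        take([
            CandidateEntity(doc_id, m.start, m.end, m.surface, "second_pass", m.hpo_ids)
            for m in find_dictionary_mentions(doc_text, augmented)
        ])
    for sent in sentences:
        if config.entity_variations:
            take(rule_entity_variations(sent, doc_text, word_lists))
        if config.longer_entities:
            pool = [c for c in candidates if c.status == "active"] + new
            take(rule_longer_entities(sent, doc_text, pool, dictionary, word_lists))
    if config.smaller_entities:
        pool = [c for c in candidates if c.status == "active"] + new
        take(rule_smaller_entities(pool, word_lists, config.split_distribute))
    return new


# --------------------------------------------------------------------------
# removal rules
# --------------------------------------------------------------------------

_WORD_RE = re.compile(r"\w+(?:['’-]\w+)*")


def _words(surface: str) -> list[str]:
    return _WORD_RE.findall(surface)


def _unbalanced(surface: str) -> bool:
    if surface.count("(") != surface.count(")"):
        return True
    return surface.count('"') % 2 == 1 or surface.count("'") % 2 == 1


def rule_general_errors(
    candidates: list[CandidateEntity], word_lists: WordLists
) -> list[CandidateEntity]:
    """Digit-only, too-short, unbalanced-bracket, and double-head-noun removals."""
    common = {normalize_surface(n) for n in word_lists.common_hpo_nouns}
    out = []
    for cand in candidates:
        if cand.status != "active":
            out.append(cand)
            continue
        surface = cand.surface.strip()
        words = _words(surface)
        if surface.replace(" ", "").isdigit():
            out.append(cand.removed("digit_only"))
        elif len(surface) < 3:
            out.append(cand.removed("too_short"))
        elif _unbalanced(surface):
            out.append(cand.removed("unbalanced_quote_or_paren"))
        elif sum(w.lower() in common for w in words) >= 2:
            out.append(cand.removed("multiple_common_nouns"))
        else:
            out.append(cand)
    return out


_FINAL_BAD_POS = {"IN", "DT", "TO", ",", "."}


def rule_incorrect_structure(candidates: list[CandidateEntity]) -> list[CandidateEntity]:
    """Remove candidates ending in a comma, dot, preposition, or determiner."""
    out = []
    for cand in candidates:
        if cand.status != "active":
            out.append(cand)
            continue
        surface = cand.surface.rstrip()
        if surface.endswith((",", ".")):
            out.append(cand.removed("bad_final_token"))
            continue
        words = _words(surface)
        if words and penn_tag(words[-1]) in _FINAL_BAD_POS:
            out.append(cand.removed("bad_final_token"))
        else:
            out.append(cand)
    return out


def rule_negative_connotation(
    candidates: list[CandidateEntity], word_lists: WordLists
) -> list[CandidateEntity]:
    """Remove exactly-two-token candidates containing a positive-connotation noun."""
    positives = {normalize_surface(n) for n in word_lists.positive_connotation_nouns}
    out = []
    for cand in candidates:
        if cand.status != "active":
            out.append(cand)
            continue
        words = _words(cand.surface)
        if len(words) == 2 and any(w.lower() in positives for w in words):
            out.append(cand.removed("positive_connotation"))
        else:
            out.append(cand)
    return out


def rule_stop_words(
    candidates: list[CandidateEntity], word_lists: WordLists
) -> list[CandidateEntity]:
    """Two stop lists: whole-surface exact matches and anywhere (partial) matches."""
    exact = set(word_lists.stop_exact)
    partial = word_lists.stop_partial
    out = []
    for cand in candidates:
        if cand.status != "active":
            out.append(cand)
            continue
        norm = normalize_surface(cand.surface)
        if norm in exact:
            out.append(cand.removed("stop_exact"))
        elif any(re.search(rf"(?<!\w){re.escape(p)}(?!\w)", norm) for p in partial):
            out.append(cand.removed("stop_partial"))
        else:
            out.append(cand)
    return out


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _attach_ids(cand: CandidateEntity, dictionary: Dictionary) -> CandidateEntity:
    if cand.hpo_ids:
        return cand
    return replace(cand, hpo_ids=frozenset(dictionary.lookup(cand.surface)))


def validate(
    crf_spans: list[tuple[int, int, str]],
    doc,
    sentences: list[Sentence],
    dictionary: Dictionary,
    word_lists: WordLists,
    config: RuleConfig | None = None,
) -> tuple[list[CandidateEntity], list[CandidateEntity]]:
    """Run the full validation pipeline on one document.

    Returns ``(final_entities, audit)``: the surviving candidates and the
    complete candidate list including removed ones with their reasons.
    Candidates are deduplicated by span; the earliest phase wins.
    """
    config = config or RuleConfig()
    doc_text = doc.text
    candidates: list[CandidateEntity] = []
    seen: set[tuple[int, int]] = set()

    def add(news: list[CandidateEntity]) -> None:
        for c in news:
            if c.span not in seen and 0 <= c.start < c.end <= len(doc_text):
                seen.add(c.span)
                candidates.append(_attach_ids(c, dictionary))

    add([
        CandidateEntity(doc.doc_id, s, e, surf, "crf")
        for (s, e, surf) in crf_spans
    ])

    if config.dictionary:
        add([
            CandidateEntity(doc.doc_id, m.start, m.end, m.surface, "dictionary", m.hpo_ids)
            for m in find_dictionary_mentions(doc_text, dictionary)
        ])
    for sent in sentences:
        if config.entity_variations:
            add(rule_entity_variations(sent, doc_text, word_lists))
    for sent in sentences:
        if config.longer_entities:
            add(rule_longer_entities(sent, doc_text, candidates, dictionary, word_lists))
    if config.smaller_entities:
        add(rule_smaller_entities(candidates, word_lists, config.split_distribute))
    if config.second_validation:
        add(rule_second_validation(
            sentences, doc_text, candidates, dictionary, word_lists, config))

    if config.boundary_trim:
        trimmed: list[CandidateEntity] = []
        for i, cand in enumerate(candidates):
            if cand.status != "active":
                continue
            m = re.match(r"^\d+\s+(?=\S)", cand.surface)
            if m:
                candidates[i] = cand.removed("leading_digit_trimmed")
                start = cand.start + m.end()
                trimmed.append(CandidateEntity(
                    cand.doc_id, start, cand.end, doc_text[start : cand.end], "split"))
        add(trimmed)

    if config.general_errors:
        candidates = rule_general_errors(candidates, word_lists)
    if config.incorrect_structure:
        candidates = rule_incorrect_structure(candidates)
    if config.negative_connotation:
        candidates = rule_negative_connotation(candidates, word_lists)
    if config.stop_words:
        candidates = rule_stop_words(candidates, word_lists)

    final = sorted(
        (c for c in candidates if c.status == "active"),
        key=lambda c: (c.start, c.end),
    )
    return final, candidates


def audit_tsv(candidates: list[CandidateEntity]) -> str:
    rows = ["doc_id\tstart\tend\tsurface\torigin\tstatus\treason"]
    for c in candidates:
        rows.append(
            f"{c.doc_id}\t{c.start}\t{c.end}\t{c.surface}\t{c.origin}"
            f"\t{c.status}\t{c.removal_reason or ''}"
        )
    return "\n".join(rows) + "\n"
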