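"""Deterministic report-processing pipeline.

Stages (in order): identifier redaction -> normalization -> concept and
date detection -> assertion-context classification -> date linking ->
relation linking.  The output is a :class:`~oncotext.types.StructuredDocument`
whose mention spans index into the redacted text.

Context classification follows a NegEx-style convention: a trigger found
in a short backward token window, with no intervening scope breaker,
flips the mention to NEGATED or HYPOTHETICAL.
"""

from __future__ import annotations

import logging
import re
from datetime import date as Date

from .dates import DATE_PHRASE_RE, parse_date_match
from .lexicon import Lexicon
from .textnorm import SCOPE_BREAKERS, SCOPE_BREAK_WORDS, NormalizedDoc
from .types import Category, ConceptMention, Context, StructuredDocument

log = logging.getLogger(__name__)

#: backward token window inspected for context triggers.
CONTEXT_WINDOW = 5
#: maximum token gap between a concept and the date phrase it links to.
DATE_LINK_WINDOW = 10

#: negation triggers, as (lemmatized) token sequences.
NEGATION_TRIGGERS: tuple[tuple[str, ...], ...] = (
    ("pas", "de"), ("absence", "de"), ("sans",), ("aucun",), ("aucune",),
)
HYPOTHESIS_TRIGGERS: tuple[tuple[str, ...], ...] = (
    ("suspicion",), ("evoque",), ("possible",), ("probable",), ("recherche", "de"),
)

_REDACTIONS = (
    (re.compile(r"[\w.+-]+@[\w-]+\.[\w.-]+"), "<EMAIL>"),
    (re.compile(r"\b(M\.|Mme|Mlle|Dr|Pr)\s+[A-ZÀ-Þ][a-zà-ÿ-]+"), r"\1 <NAME>"),
    (re.compile(r"\d{6,}"), "<ID>"),
)


def redact_identifiers(text: str) -> str:
    """Replace person names, long digit runs and e-mails by typed placeholders.

    Idempotent: placeholders contain nothing the patterns re-match.
    """
    for pattern, repl in _REDACTIONS:
        text = pattern.sub(repl, text)
    return text


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_dates(doc: NormalizedDoc, doc_id: str) -> list[ConceptMention]:
    """Find date phrases; unparseable surfaces are dropped with a log line."""
    mentions: list[ConceptMention] = []
    for m in DATE_PHRASE_RE.finditer(doc.norm):
        value = parse_date_match(m)
        if value is None:
            log.warning("dropping unparseable date %r in %s", m.group(0), doc_id)
            continue
        start, end = doc.orig_span(m.start(), m.end())
        mentions.append(ConceptMention(doc_id, start, end, Category.DATE,
                                       linked_date=value))
    return mentions


def detect_mentions(doc: NormalizedDoc, lex: Lexicon, doc_id: str,
                    consumed: set[int] | None = None) -> list[ConceptMention]:
    """Longest-match-first, left-to-right, non-overlapping lexicon matching.

    ``consumed`` is a set of token indices already claimed (by date
    phrases); matches may not cross them.  Spans are reported in original
    (redacted-text) coordinates.
    """
    if len(lex) == 0:
        raise ValueError("lexicon is empty")
    consumed = consumed or set()
    toks = doc.tokens
    mentions: list[ConceptMention] = []
    i = 0
    n = len(toks)
    while i < n:
        if i in consumed:
            i += 1
            continue
        hit = None
        max_l = min(lex.max_tokens, n - i)
        for length in range(max_l, 0, -1):
            if any((i + j) in consumed for j in range(length)):
                continue
            key = tuple(t.lemma for t in toks[i:i + length])
            entry = lex.lookup_key(key)
            if entry is not None:
                hit = (length, entry)
                break
        if hit is None:
            i += 1
            continue
        length, entry = hit
        start, end = doc.orig_span(toks[i].start, toks[i + length - 1].end)
        mentions.append(ConceptMention(doc_id, start, end, entry.category,
                                       code=entry.code))
        i += length
    return mentions


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def _window_before(doc: NormalizedDoc, tok_start: int) -> list[str]:
    """Tokens in the backward window, truncated at the last scope breaker."""
    window: list[str] = []
    for j in range(tok_start - 1, max(tok_start - CONTEXT_WINDOW, 0) - 1, -1):
        tok = doc.tokens[j].text
        if tok in SCOPE_BREAKERS or tok in SCOPE_BREAK_WORDS:
            break
        window.append(tok)
    window.reverse()
    return window


def _has_trigger(window: list[str], triggers: tuple[tuple[str, ...], ...]) -> bool:
    for trig in triggers:
        k = len(trig)
        for i in range(len(window) - k + 1):
            if tuple(window[i:i + k]) == trig:
                return True
    return False


def classify_context(mention: ConceptMention, doc: NormalizedDoc) -> Context:
    """NEGATED/HYPOTHETICAL by backward trigger search, else AFFIRMED."""
    if mention.category is Category.DATE:
        return Context.AFFIRMED
    t0 = _mention_token_range(mention, doc)[0]
    window = _window_before(doc, t0)
    if _has_trigger(window, NEGATION_TRIGGERS):
        return Context.NEGATED
    if _has_trigger(window, HYPOTHESIS_TRIGGERS):
        return Context.HYPOTHETICAL
    return Context.AFFIRMED


def _mention_token_range(mention: ConceptMention, doc: NormalizedDoc) -> tuple[int, int]:
    """(first token index, last token index + 1) of a mention."""
    first = last = None
    for i, t in enumerate(doc.tokens):
        o_start, o_end = doc.orig_span(t.start, t.end)
        if o_end <= mention.start:
            continue
        if o_start >= mention.end:
            break
        if first is None:
            first = i
        last = i
    if first is None:
        raise ValueError("mention spans no tokens")
    return first, last + 1


# ---------------------------------------------------------------------------
# date + relation linking
# ---------------------------------------------------------------------------

def attach_dates(mentions: list[ConceptMention], doc: NormalizedDoc) -> None:
    """Link each concept to the nearest same-sentence date phrase.

    Distance is the number of tokens strictly between the mention and the
    date; candidates beyond :data:`DATE_LINK_WINDOW` are ignored.  Ties go
    to the leftmost date.  Mentions with no candidate keep ``linked_date``
    None (the document date is the downstream fallback).
    """
    ranges = [_mention_token_range(m, doc) for m in mentions]
    sentences = [doc.tokens[r[0]].sentence for r in ranges]
    date_idx = [i for i, m in enumerate(mentions) if m.category is Category.DATE]
    for i, m in enumerate(mentions):
        if m.category is Category.DATE:
            continue
        best: tuple[int, int] | None = None  # (gap, date position)
        for j in date_idx:
            if sentences[j] != sentences[i]:
                continue
            gap = _token_gap(ranges[i], ranges[j])
            if gap > DATE_LINK_WINDOW:
                continue
            key = (gap, ranges[j][0])
            if best is None or key < best:
                best = key
                m.linked_date = mentions[j].linked_date
        if best is None:
            m.linked_date = None


def _token_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    if b[0] >= a[1]:
        return b[0] - a[1]
    if a[0] >= b[1]:
        return a[0] - b[1]
    return 0


def link_relations(mentions: list[ConceptMention], doc: NormalizedDoc) -> None:
    """Sentence-scoped entity linking.

    A treatment response links to the nearest treatment mention in its
    sentence (preferring a preceding one); a metastasis links to a tumor
    location in its sentence when one is present.
    """
    ranges = [_mention_token_range(m, doc) for m in mentions]
    sentences = [doc.tokens[r[0]].sentence for r in ranges]

    def nearest(i: int, target: Category) -> int | None:
        best: tuple[int, int, int] | None = None  # (not-preceding, gap, j)
        for j, m in enumerate(mentions):
            if j == i or m.category is not target or sentences[j] != sentences[i]:
                continue
            preceding = 0 if ranges[j][0] < ranges[i][0] else 1
            key = (preceding, _token_gap(ranges[i], ranges[j]), j)
            if best is None or key < best:
                best = key
        return best[2] if best else None

    for i, m in enumerate(mentions):
        if m.category is Category.TREATMENT_RESPONSE:
            m.related_to = nearest(i, Category.TREATMENT)
        elif m.category is Category.METASTASIS:
            m.related_to = nearest(i, Category.TUMOR_LOCATION)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

REQUIRED_FIELDS = ("doc_id", "patient_id", "doc_date", "text")


def process_document(record: dict, lex: Lexicon) -> StructuredDocument:
    """Run the full pipeline on one raw document record.

    ``record`` needs ``doc_id``, ``patient_id``, ``doc_date`` (ISO string
    or :class:`datetime.date`) and ``text``.
    """
    for f in REQUIRED_FIELDS:
        if f not in record or record[f] is None:
            raise ValueError(f"document record missing field: {f}")
    doc_date = record["doc_date"]
    if isinstance(doc_date, str):
        doc_date = Date.fromisoformat(doc_date)

    redacted = redact_identifiers(record["text"])
    doc = NormalizedDoc(redacted)

    date_mentions = detect_dates(doc, record["doc_id"])
    consumed: set[int] = set()
    for m in date_mentions:
        t0, t1 = _mention_token_range(m, doc)
        consumed.update(range(t0, t1))
    concept_mentions = detect_mentions(doc, lex, record["doc_id"], consumed)

    mentions = sorted(date_mentions + concept_mentions, key=lambda m: m.start)
    for m in mentions:
        m.context = classify_context(m, doc)
    attach_dates(mentions, doc)
    link_relations(mentions, doc)

    sd = StructuredDocument(record["doc_id"], record["patient_id"], doc_date,
                            mentions, redacted)
    sd.validate()
    return sd
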