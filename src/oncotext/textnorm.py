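"""Text normalization with offset tracking, tokenization and lemmatization.

Normalization lowercases, strips diacritics, unifies apostrophes and
collapses whitespace runs; an offset map converts every normalized character
position back to a span in the original text, so all mention spans can be
reported in original coordinates.  The original text is never mutated.

Lemmatization is a deliberately small suffix-stripping rule (French plural
``-s``/``-x``) — enough for a lexicon-closed vocabulary, applied only while
matching, never to reported text.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

APOSTROPHES = {"’": "'", "‘": "'", "ʼ": "'"}
LIGATURES = {"œ": "oe", "æ": "ae", "Œ": "oe", "Æ": "ae"}

#: common French function words; retained during phrase matching (the
#: vocabulary's own phrases contain them) but exposed for token filtering.
STOPWORDS = frozenset(
    "le la les un une des de du au aux et ou a d l en pour par sur avec".split()
)

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

#: punctuation that breaks assertion scope (negation/hypothesis windows).
SCOPE_BREAKERS = frozenset({",", ".", ";", ":", "!", "?", "(", ")"})
#: adversative conjunction: also breaks scope.
SCOPE_BREAK_WORDS = frozenset({"mais"})

_SENTENCE_END = frozenset({".", "!", "?"})


def _norm_char(ch: str) -> str:
    """Normalize a single character to zero or more lowercase ASCII-ish chars."""
    if ch in APOSTROPHES:
        return "'"
    if ch in LIGATURES:
        return LIGATURES[ch]
    decomposed = unicodedata.normalize("NFD", ch)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return stripped.lower()


def normalize_text(text: str) -> tuple[str, list[tuple[int, int]]]:
    """Return ``(normalized, spans)``.

    ``spans[i]`` is the half-open span in the *original* text that produced
    normalized character ``i``.  Whitespace runs collapse to a single space
    mapped to the first whitespace character; leading and trailing
    whitespace is dropped.
    """
    out: list[str] = []
    spans: list[tuple[int, int]] = []
    pending_ws: int | None = None
    for i, ch in enumerate(text):
        if ch.isspace():
            if pending_ws is None:
                pending_ws = i
            continue
        if pending_ws is not None:
            if out:  # no leading space
                out.append(" ")
                spans.append((pending_ws, pending_ws + 1))
            pending_ws = None
        for c in _norm_char(ch):
            out.append(c)
            spans.append((i, i + 1))
    return "".join(out), spans


def lemma(token: str) -> str:
    """Suffix-stripping lemma: drop a final plural ``s``/``x`` on long words."""
    if token.isalpha() and len(token) > 3 and token[-1] in "sx":
        return token[:-1]
    return token


@dataclass(frozen=True)
class Token:
    text: str
    start: int  # normalized coordinates
    end: int
    lemma: str
    sentence: int


class NormalizedDoc:
    """A document's normalized view: text, offset map, tokens, sentences."""

    def __init__(self, original: str):
        self.original = original
        self.norm, self._spans = normalize_text(original)
        self.tokens: list[Token] = []
        sent = 0
        for m in _TOKEN_RE.finditer(self.norm):
            tok = m.group(0)
            self.tokens.append(Token(tok, m.start(), m.end(), lemma(tok), sent))
            if tok in _SENTENCE_END:
                sent += 1

    def orig_span(self, norm_start: int, norm_end: int) -> tuple[int, int]:
        """Map a normalized half-open span back to original coordinates."""
        if norm_start >= norm_end:
            raise ValueError("empty span")
        return self._spans[norm_start][0], self._spans[norm_end - 1][1]

    def token_index_at(self, norm_pos: int) -> int:
        """Index of the token containing or starting at ``norm_pos``."""
        for i, t in enumerate(self.tokens):
            if t.end > norm_pos:
                return i
        return len(self.tokens)
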