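"""Independent reference implementations used as test oracles.

Written deliberately as naive loops, sharing no code path with the
package implementations they check.
"""

from __future__ import annotations

import re
import unicodedata
from datetime import date as Date
from datetime import timedelta

from oncotext.config import OnsetParams
from oncotext.types import Category, ConceptOccurrence, Context


def brute_force_onset(occurrences: list[ConceptOccurrence],
                      params: OnsetParams) -> Date | None:
    """Exhaustive window enumeration: every candidate start date, every
    occurrence re-scanned per window, first window over threshold wins."""
    cands = []
    for o in occurrences:
        if o.context is Context.NEGATED:
            continue
        if o.category is Category.METASTASIS or (
                o.category is Category.RELAPSE and o.code == "DISTANT"):
            cands.append(o)
    for start in sorted({o.date for o in cands}):
        total = 0.0
        for o in cands:
            if start <= o.date < start + timedelta(days=params.interval_days):
                w = params.source_weight[o.source] * params.date_origin_weight[o.date_origin]
                if o.context is Context.HYPOTHETICAL:
                    w = w * params.hypothetical_weight
                total = total + w
        if total > params.threshold:
            return start
    return None


def char_walk_normalize(text: str) -> tuple[str, dict[int, int]]:
    """Character-walk normalization reference: returns the normalized
    string and a map from each normalized index to its original index."""
    out = []
    mapping = {}
    i = 0
    n = len(text)
    while i < n and text[i].isspace():
        i += 1
    ws_start = None
    while i < n:
        ch = text[i]
        if ch.isspace():
            if ws_start is None:
                ws_start = i
            i += 1
            continue
        if ws_start is not None:
            mapping[len(out)] = ws_start
            out.append(" ")
            ws_start = None
        ch = {"’": "'", "‘": "'", "ʼ": "'", "œ": "oe", "æ": "ae",
              "Œ": "oe", "Æ": "ae"}.get(ch, ch)
        for c in ch:
            c2 = "".join(x for x in unicodedata.normalize("NFD", c)
                         if not unicodedata.combining(x)).lower()
            for y in c2:
                mapping[len(out)] = i
                out.append(y)
        i += 1
    return "".join(out), mapping


def token_gap_oracle(norm_text: str, span_a: tuple[int, int],
                     span_b: tuple[int, int]) -> int:
    """Number of tokens strictly between two normalized-coordinate spans."""
    tokens = [(m.start(), m.end()) for m in re.finditer(r"\w+|[^\w\s]", norm_text)]
    lo, hi = sorted([span_a, span_b])
    return sum(1 for s, e in tokens if s >= lo[1] and e <= hi[0])
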