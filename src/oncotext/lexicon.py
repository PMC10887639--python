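"""Terminology lexicon: normalized surface forms mapped to categories/codes.

Entries are stored under their lemmatized token sequence, so inflectional
variants present in reports ("métastases", "Métastase") resolve to the same
entry.  The CSV interchange format is ``term,category,code,code_system``
(UTF-8, header row).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .textnorm import lemma, normalize_text
from .types import Category, CodeSystem


@dataclass(frozen=True)
class LexiconEntry:
    term: str  # normalized surface form
    category: Category
    code: str | None
    code_system: CodeSystem


class Lexicon:
    def __init__(self) -> None:
        self._by_term: dict[str, LexiconEntry] = {}
        self._by_key: dict[tuple[str, ...], LexiconEntry] = {}
        self.max_tokens = 0

    def __len__(self) -> int:
        return len(self._by_term)

    def __contains__(self, term: str) -> bool:
        """Membership under the same normalization + lemmatization as
        matching, so inflectional variants of a term are members too."""
        return self._key(self._normalize(term)) in self._by_key

    @staticmethod
    def _normalize(term: str) -> str:
        norm, _ = normalize_text(term)
        return norm

    @staticmethod
    def _key(norm_term: str) -> tuple[str, ...]:
        import re

        return tuple(lemma(t) for t in re.findall(r"\w+|[^\w\s]", norm_term))

    def add(self, term: str, category: Category, code: str | None = None,
            code_system: CodeSystem = CodeSystem.NONE) -> None:
        norm = self._normalize(term)
        if not norm:
            raise ValueError("empty term")
        if norm in self._by_term:
            raise ValueError(f"duplicate lexicon term: {norm!r}")
        entry = LexiconEntry(norm, category, code, code_system)
        key = self._key(norm)
        if key in self._by_key:
            raise ValueError(f"term {norm!r} collides with {self._by_key[key].term!r} after lemmatization")
        self._by_term[norm] = entry
        self._by_key[key] = entry
        self.max_tokens = max(self.max_tokens, len(key))

    def lookup_key(self, key: tuple[str, ...]) -> LexiconEntry | None:
        return self._by_key.get(key)

    def entries(self) -> list[LexiconEntry]:
        return sorted(self._by_term.values(), key=lambda e: e.term)

    # -- CSV interchange ----------------------------------------------------

    def to_csv(self, path: str) -> None:
        rows = [
            {"term": e.term, "category": e.category.value,
             "code": e.code or "", "code_system": e.code_system.value}
            for e in self.entries()
        ]
        pd.DataFrame(rows, columns=["term", "category", "code", "code_system"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str) -> "Lexicon":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        lex = cls()
        for _, row in df.iterrows():
            lex.add(
                row["term"],
                Category(row["category"]),
                row["code"] or None,
                CodeSystem(row["code_system"]) if row.get("code_system") else CodeSystem.NONE,
            )
        return lex
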