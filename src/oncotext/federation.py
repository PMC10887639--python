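"""Per-centre cohort queries and count-only federation.

A query mixes a textual criterion (keyword phrases matched accent- and
case-insensitively against raw report text) with structured criteria
evaluated on the inferred patient profiles.  Federation runs the query
locally at every centre and aggregates nothing but counts: no patient
identifier crosses the aggregation boundary.

Keyword matching deliberately runs on raw document text rather than on
context-filtered mentions — it is a textual search, and the unknown-
primary keyword list itself contains phrases with embedded negation
wording ("pas de primitif retrouve").
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from datetime import date as Date

from pydantic import BaseModel, ConfigDict, model_validator

from .config import QuerySettings
from .terminology import CUP_KEYWORDS
from .textnorm import NormalizedDoc
from .types import EventKind, PatientProfile

log = logging.getLogger(__name__)


class Combine(str, enum.Enum):
    ALL = "ALL"
    ANY = "ANY"


class CohortQuery(BaseModel):
    """Declarative cohort selection criteria."""

    model_config = ConfigDict(frozen=True)

    keyword_terms: tuple[str, ...] | None = None
    since_date: Date | None = None
    metastatic_at_diagnosis: bool | None = None
    required_site: str | None = None
    combine: Combine = Combine.ALL

    @model_validator(mode="after")
    def _at_least_one(self) -> "CohortQuery":
        if (self.keyword_terms is None and self.since_date is None
                and self.metastatic_at_diagnosis is None
                and self.required_site is None):
            raise ValueError("query needs at least one non-null criterion")
        return self


def cup_query(refined: bool = False) -> CohortQuery:
    """The cancer-of-unknown-primary cohort query.

    The base form searches the single phrase "primitif inconnu" among
    patients diagnosed de novo metastatic since 2010-01-01.  The refined
    form widens the textual criterion to the full ten-phrase keyword
    list (any phrase suffices; the structured criteria still all apply).
    """
    terms = tuple(CUP_KEYWORDS) if refined else ("primitif inconnu",)
    return CohortQuery(
        keyword_terms=terms,
        since_date=Date(2010, 1, 1),
        metastatic_at_diagnosis=True,
        combine=Combine.ALL,
    )


# ---------------------------------------------------------------------------
# centre store + local execution
# ---------------------------------------------------------------------------

def _phrase_key(phrase: str) -> tuple[str, ...]:
    doc = NormalizedDoc(phrase)
    return tuple(t.lemma for t in doc.tokens)


def _contains(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    k = len(needle)
    if k == 0:
        return False
    return any(haystack[i:i + k] == needle for i in range(len(haystack) - k + 1))


@dataclass
class CentreStore:
    """One centre's queryable state: profiles plus a raw-text token index."""

    centre_id: str
    profiles: dict[str, PatientProfile]
    documents: dict[str, list[str]]  # patient_id -> raw report texts
    _token_index: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, texts in self.documents.items():
            self._token_index[pid] = [
                tuple(t.lemma for t in NormalizedDoc(text).tokens) for text in texts
            ]

    def patient_ids(self) -> list[str]:
        return sorted(set(self.profiles) | set(self.documents))

    def has_phrase(self, pid: str, needles: list[tuple[str, ...]]) -> bool:
        return any(_contains(toks, n)
                   for toks in self._token_index.get(pid, ())
                   for n in needles)


def run_local(store: CentreStore, q: CohortQuery,
              settings: QuerySettings | None = None) -> tuple[int, list[str]]:
    """Evaluate a query at one centre; returns (count, local patient ids)."""
    settings = settings or QuerySettings()
    needles = [_phrase_key(p) for p in (q.keyword_terms or ())]

    def de_novo(profile: PatientProfile | None) -> bool:
        if profile is None:
            return False
        for c in profile.cancers:
            for e in c.tumor_events:
                if (e.kind is EventKind.METASTATIC_RELAPSE
                        and abs((e.date - c.diagnosis_date).days)
                        <= settings.de_novo_window_days):
                    return True
        return False

    matched: list[str] = []
    for pid in store.patient_ids():
        profile = store.profiles.get(pid)
        checks: list[bool] = []
        if q.keyword_terms is not None:
            checks.append(store.has_phrase(pid, needles))
        if q.since_date is not None:
            checks.append(profile is not None and any(
                c.diagnosis_date >= q.since_date for c in profile.cancers))
        if q.metastatic_at_diagnosis is not None:
            checks.append(de_novo(profile) == q.metastatic_at_diagnosis)
        if q.required_site is not None:
            checks.append(profile is not None and any(
                c.primary_site == q.required_site for c in profile.cancers))
        ok = all(checks) if q.combine is Combine.ALL else any(checks)
        if ok:
            matched.append(pid)
    return len(matched), matched


@dataclass
class FederatedCounts:
    per_centre: dict[str, int]
    total: int
    unreachable: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {"per_centre": dict(sorted(self.per_centre.items())),
                     "total": self.total}
        if self.unreachable:
            out["unreachable"] = sorted(self.unreachable)
        return out


def federate(stores: list[CentreStore], q: CohortQuery,
             settings: QuerySettings | None = None) -> FederatedCounts:
    """Count-only aggregation across centres.

    A centre whose local run fails is omitted from the total and reported
    in ``unreachable``.  Only counts leave each centre.
    """
    if not stores:
        raise ValueError("federation needs at least one centre")
    per_centre: dict[str, int] = {}
    unreachable: list[str] = []
    for store in stores:
        try:
            count, _ = run_local(store, q, settings)
        except Exception:  # noqa: BLE001 — an unreachable centre is reported, not fatal
            log.exception("centre %s unreachable", store.centre_id)
            unreachable.append(store.centre_id)
            continue
        per_centre[store.centre_id] = count
    return FederatedCounts(per_centre, sum(per_centre.values()), unreachable)


def query_from_dict(raw: dict) -> CohortQuery:
    """Build a query from a YAML/JSON mapping; supports CUP presets."""
    preset = raw.get("preset")
    if preset == "cup_base":
        return cup_query(refined=False)
    if preset == "cup_refined":
        return cup_query(refined=True)
    return CohortQuery.model_validate({k: v for k, v in raw.items() if k != "preset"})


__all__ = [
    "CentreStore", "CohortQuery", "Combine", "FederatedCounts",
    "cup_query", "federate", "query_from_dict", "run_local",
]
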