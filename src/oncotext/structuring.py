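"""Inferred model: from occurrence soup to a structured patient profile.

The rule order is fixed: deduplicate -> corroborate against discharge
data -> resolve the primary tumor -> date the metastasis onset (only when
onset candidates exist) -> assemble acts.  The onset heuristic slides a
time window over the dated metastasis/distant-relapse occurrences,
accumulating per-occurrence weights (by source, date origin and
assertion context) and accepts the first window whose total weight
clears a threshold; the window's start date is the inferred onset.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left
from collections import Counter
from datetime import timedelta

from .codes import act_types_for, prefix3
from .config import OnsetParams
from .types import (
    UNKNOWN_PRIMARY,
    ActRecord,
    Cancer,
    Category,
    ConceptOccurrence,
    Context,
    DateOrigin,
    EventKind,
    OnsetDiagnostics,
    PatientProfile,
    SourceKind,
    TreatmentType,
    TumorEvent,
    WindowDiagnostic,
)

#: corroboration window: a coded stay within this many days of a report
#: mention counts as confirmation.
CORROBORATION_DAYS = 90

#: ICD-10 C80 = malignant neoplasm, unspecified site — the coded face of
#: an unidentified primary; never a resolvable location.
_UNSPECIFIED_SITE_PREFIX = "C80"


def deduplicate_occurrences(occurrences: list[ConceptOccurrence]) -> list[ConceptOccurrence]:
    """Collapse occurrences identical on (category, code, date, context).

    The representative is the one with the richest provenance: a
    concept-linked date beats a document-date fallback, coded discharge
    data beats report text, then the smallest source id.  Idempotent;
    never increases the count.
    """
    def rank(o: ConceptOccurrence) -> tuple:
        return (
            0 if o.date_origin is DateOrigin.CONCEPT_LINKED else 1,
            0 if o.source is SourceKind.PMSI else 1,
            o.source_id,
            o.occurrence_id,
        )

    best: dict[tuple, ConceptOccurrence] = {}
    for o in occurrences:
        key = (o.category, o.code, o.date, o.context)
        cur = best.get(key)
        if cur is None or rank(o) < rank(cur):
            best[key] = o
    out = list(best.values())
    out.sort(key=lambda o: (o.date, o.source_id, o.occurrence_id))
    return out


def corroborate_with_discharge(occurrences: list[ConceptOccurrence]) -> list[ConceptOccurrence]:
    """Flag report occurrences confirmed by a compatible coded stay.

    A report diagnosis matches a discharge diagnosis sharing its 3-character
    ICD-10 category; a report treatment matches a coded act/encounter of
    the same treatment type; a report metastasis matches any coded
    secondary-malignancy occurrence.  In every case the stay must lie
    within ±90 days.  Flags are monotone in the discharge data.
    """
    pmsi = [o for o in occurrences if o.source is SourceKind.PMSI]
    window = timedelta(days=CORROBORATION_DAYS)

    def near(o: ConceptOccurrence, p: ConceptOccurrence) -> bool:
        return abs((o.date - p.date).days) <= window.days

    treatment_types = {t.value for t in TreatmentType}
    out: list[ConceptOccurrence] = []
    for o in occurrences:
        flag = o.corroborated
        if not flag and o.source is SourceKind.REPORT:
            if o.category is Category.TUMOR_LOCATION and o.code:
                flag = any(p.category is Category.TUMOR_LOCATION
                           and p.code and prefix3(p.code) == prefix3(o.code)
                           and near(o, p) for p in pmsi)
            elif o.category is Category.METASTASIS:
                flag = any(p.category is Category.METASTASIS and near(o, p)
                           for p in pmsi)
            elif o.category is Category.TREATMENT and o.code in treatment_types:
                ttype = TreatmentType(o.code)
                flag = any(p.category is Category.TREATMENT and p.code
                           and ttype in act_types_for(p.code) and near(o, p)
                           for p in pmsi)
        out.append(dataclasses.replace(o, corroborated=flag) if flag != o.corroborated else o)
    return out


# ---------------------------------------------------------------------------
# metastasis onset heuristic
# ---------------------------------------------------------------------------

def onset_candidates(occurrences: list[ConceptOccurrence]) -> list[ConceptOccurrence]:
    """Metastasis and distant-relapse occurrences, negations excluded."""
    return [
        o for o in occurrences
        if o.context is not Context.NEGATED
        and (o.category is Category.METASTASIS
             or (o.category is Category.RELAPSE and o.code == "DISTANT"))
    ]


def infer_metastasis_onset(occurrences: list[ConceptOccurrence],
                           params: OnsetParams) -> OnsetDiagnostics:
    """Weighted sliding-interval dating of the metastatic phase.

    Windows start at each distinct candidate date in chronological order
    and span ``params.interval_days``; each candidate contributes
    ``source_weight x date_origin_weight`` (down-weighted if
    hypothetical).  The first window whose cumulative weight exceeds
    ``params.threshold`` is accepted and its start date is the inferred
    onset; with no such window the onset stays undetermined.
    """
    cands = onset_candidates(occurrences)
    diag = OnsetDiagnostics()
    if not cands:
        return diag

    cands.sort(key=lambda o: (o.date, o.source_id, o.occurrence_id))
    dates = [o.date for o in cands]
    weights = [
        params.weight_of(o.source, o.date_origin, o.context is Context.HYPOTHETICAL)
        for o in cands
    ]
    span = timedelta(days=params.interval_days)

    chosen = None
    for start in sorted(set(dates)):
        lo = bisect_left(dates, start)
        hi = bisect_left(dates, start + span)
        total = sum(weights[lo:hi])
        accepted = chosen is None and total > params.threshold
        if accepted:
            chosen = start
        diag.windows.append(WindowDiagnostic(start, total, accepted))
    diag.chosen_onset = chosen
    return diag


# ---------------------------------------------------------------------------
# profile assembly
# ---------------------------------------------------------------------------

def _most_frequent_code(occ: list[ConceptOccurrence]) -> str | None:
    counts = Counter(o.code for o in occ if o.code)
    if not counts:
        return None
    # ties break to the lexicographically smallest code, for determinism
    return min(counts, key=lambda c: (-counts[c], c))


def build_profile(occurrences: list[ConceptOccurrence],
                  params: OnsetParams) -> PatientProfile:
    profile, _ = build_profile_with_diagnostics(occurrences, params)
    return profile


def build_profile_with_diagnostics(
    occurrences: list[ConceptOccurrence], params: OnsetParams,
) -> tuple[PatientProfile, OnsetDiagnostics]:
    """Run the full structuring rule sequence for one patient."""
    if not occurrences:
        return PatientProfile(patient_id=""), OnsetDiagnostics()
    patient_id = occurrences[0].patient_id

    occ = deduplicate_occurrences(occurrences)
    occ = corroborate_with_discharge(occ)

    # -- primary tumor resolution ------------------------------------------
    def resolvable(o: ConceptOccurrence) -> bool:
        return (o.category is Category.TUMOR_LOCATION
                and o.context is Context.AFFIRMED and o.code is not None
                and prefix3(o.code) != _UNSPECIFIED_SITE_PREFIX)

    affirmed_locs = [o for o in occ if resolvable(o)]
    confirmed = [o for o in affirmed_locs
                 if o.corroborated or o.source is SourceKind.PMSI]
    primary = _most_frequent_code(confirmed) or _most_frequent_code(affirmed_locs)

    up_keywords = [o for o in occ
                   if o.category is Category.UNKNOWN_PRIMARY_KEYWORD
                   and o.context is not Context.NEGATED]

    cancers: list[Cancer] = []
    onset_diag = OnsetDiagnostics()
    if primary is not None or up_keywords:
        if primary is not None:
            site = primary
            mine = [o for o in affirmed_locs if o.code == primary]
            diagnosis_date = min(o.date for o in mine)
            support = [o.occurrence_id for o in mine]
        else:
            site = UNKNOWN_PRIMARY
            basis = up_keywords + [
                o for o in occ if o.category is Category.METASTASIS
                and o.context is Context.AFFIRMED
            ]
            diagnosis_date = min(o.date for o in basis)
            support = [o.occurrence_id for o in up_keywords]

        morph = _most_frequent_code([
            o for o in occ if o.category is Category.MORPHOLOGY
            and o.context is Context.AFFIRMED
        ])

        events = [TumorEvent(EventKind.PRIMARY, diagnosis_date, sorted(support))]

        for d in sorted({o.date for o in occ
                         if o.category is Category.RELAPSE and o.code == "LOCAL"
                         and o.context is Context.AFFIRMED}):
            events.append(TumorEvent(
                EventKind.LOCAL_RELAPSE, d,
                [o.occurrence_id for o in occ
                 if o.category is Category.RELAPSE and o.code == "LOCAL"
                 and o.date == d],
            ))

        # the onset rule only fires when candidate occurrences exist
        cands = onset_candidates(occ)
        if cands:
            onset_diag = infer_metastasis_onset(occ, params)
            if onset_diag.chosen_onset is not None:
                event_date = max(onset_diag.chosen_onset, diagnosis_date)
                end = onset_diag.chosen_onset + timedelta(days=params.interval_days)
                support_met = sorted(
                    o.occurrence_id for o in cands
                    if onset_diag.chosen_onset <= o.date < end
                )
                events.append(TumorEvent(EventKind.METASTATIC_RELAPSE,
                                         event_date, support_met))

        rank = {EventKind.PRIMARY: 0, EventKind.LOCAL_RELAPSE: 1,
                EventKind.METASTATIC_RELAPSE: 2}
        events.sort(key=lambda e: (e.date, rank[e.kind]))
        cancers.append(Cancer(site, morph, diagnosis_date, events))

    # -- acts ---------------------------------------------------------------
    acts = [
        ActRecord(o.code, o.date, o.corroborated, [o.occurrence_id])
        for o in occ
        if o.category is Category.TREATMENT and o.source is SourceKind.REPORT
        and o.context is Context.AFFIRMED and o.code is not None
    ]
    acts.sort(key=lambda a: (a.date, a.type))

    document_ids = sorted({o.source_id for o in occ
                           if o.source is SourceKind.REPORT})

    profile = PatientProfile(patient_id, cancers, acts, document_ids)
    profile.validate()
    return profile, onset_diag
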