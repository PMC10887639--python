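"""Elementary (pivot) model: a per-patient store of concept occurrences.

Each occurrence keeps full provenance — source kind and id, the date and
how it was obtained (concept-linked vs document fallback), and when it was
recorded.  Ingestion is additive and order-independent: the store behaves
as a set keyed on occurrence identity.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .codes import is_secondary_malignancy, is_valid_ccam, is_valid_icd10
from .io import occurrence_from_dict, occurrence_to_dict, read_jsonl, write_jsonl
from .types import (
    Category,
    ConceptOccurrence,
    Context,
    DateOrigin,
    DischargeRecord,
    SourceKind,
    StructuredDocument,
)

log = logging.getLogger(__name__)


def ingest_document(sd: StructuredDocument) -> list[ConceptOccurrence]:
    """One occurrence per non-DATE mention.

    The occurrence date is the mention's linked date when the text carried
    one (origin CONCEPT_LINKED), else the document date (origin DOCUMENT).
    """
    sd.validate()
    out: list[ConceptOccurrence] = []
    k = 0
    for m in sd.mentions:
        if m.category is Category.DATE:
            continue
        if m.linked_date is not None:
            date, origin = m.linked_date, DateOrigin.CONCEPT_LINKED
        else:
            date, origin = sd.doc_date, DateOrigin.DOCUMENT
        out.append(ConceptOccurrence(
            occurrence_id=f"{sd.doc_id}:{k}",
            patient_id=sd.patient_id,
            category=m.category,
            code=m.code,
            context=m.context,
            date=date,
            date_origin=origin,
            source=SourceKind.REPORT,
            source_id=sd.doc_id,
            recorded_at=sd.doc_date,
        ))
        k += 1
    return out


def ingest_discharge(r: DischargeRecord) -> list[ConceptOccurrence]:
    """Occurrences from a coded stay: one per diagnosis code and per act.

    Codes in the C77–C79 block become METASTASIS, other C-codes
    TUMOR_LOCATION, session-encounter Z-codes TREATMENT; coded billing
    data carries no textual context, so everything is AFFIRMED and dated
    at admission.  A malformed code skips the whole record with a warning.
    """
    r.validate()
    codes = [r.main_dx_icd10, *r.associated_dx_icd10]
    for c in codes:
        if not is_valid_icd10(c):
            log.warning("skipping stay %s: malformed ICD-10 code %r", r.stay_id, c)
            return []
    for a in r.acts_ccam:
        if not is_valid_ccam(a):
            log.warning("skipping stay %s: malformed CCAM code %r", r.stay_id, a)
            return []

    out: list[ConceptOccurrence] = []
    k = 0

    def emit(category: Category, code: str) -> None:
        nonlocal k
        out.append(ConceptOccurrence(
            occurrence_id=f"{r.stay_id}:{k}",
            patient_id=r.patient_id,
            category=category,
            code=code,
            context=Context.AFFIRMED,
            date=r.admission_date,
            date_origin=DateOrigin.DOCUMENT,
            source=SourceKind.PMSI,
            source_id=r.stay_id,
            recorded_at=r.discharge_date,
        ))
        k += 1

    for c in codes:
        if is_secondary_malignancy(c):
            emit(Category.METASTASIS, c)
        elif c.startswith("C"):
            emit(Category.TUMOR_LOCATION, c)
        elif c.startswith("Z51"):
            emit(Category.TREATMENT, c)
        # other non-oncology codes carry no concept of interest
    for a in r.acts_ccam:
        emit(Category.TREATMENT, a)
    return out


class PivotStore:
    """In-memory occurrence store with JSONL round-trip."""

    def __init__(self) -> None:
        self._by_patient: dict[str, dict[tuple, ConceptOccurrence]] = {}

    def add(self, occurrences: list[ConceptOccurrence]) -> None:
        for o in occurrences:
            self._by_patient.setdefault(o.patient_id, {})[o.identity()] = o

    def ingest_document(self, sd: StructuredDocument) -> list[ConceptOccurrence]:
        occ = ingest_document(sd)
        self.add(occ)
        return occ

    def ingest_discharge(self, r: DischargeRecord) -> list[ConceptOccurrence]:
        occ = ingest_discharge(r)
        self.add(occ)
        return occ

    def patients(self) -> list[str]:
        return sorted(self._by_patient)

    def occurrences_for_patient(self, patient_id: str) -> list[ConceptOccurrence]:
        """Chronologically sorted (date, source_id, occurrence_id); stable.

        Unknown patients yield an empty list, not an error.
        """
        occ = list(self._by_patient.get(patient_id, {}).values())
        occ.sort(key=lambda o: (o.date, o.source_id, o.occurrence_id))
        return occ

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_patient.values())

    # -- persistence --------------------------------------------------------

    def dump(self, path: str | Path) -> None:
        rows = (occurrence_to_dict(o)
                for pid in self.patients()
                for o in self.occurrences_for_patient(pid))
        write_jsonl(path, rows)

    @classmethod
    def load(cls, path: str | Path) -> "PivotStore":
        store = cls()
        store.add([occurrence_from_dict(row) for row in read_jsonl(path)])
        return store
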