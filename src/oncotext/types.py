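"""Core domain types shared across the pipeline.

The package models oncology data at three levels:

* raw level — synthetic medical reports (:class:`SyntheticDocument`) and
  hospital-discharge records (:class:`DischargeRecord`);
* elementary level — document-centric :class:`ConceptOccurrence` atoms with
  full provenance (which source, which date, how the date was obtained);
* inferred level — the patient-centric :class:`PatientProfile` hierarchy
  (cancer -> tumor events -> acts -> documents).

All dates are :class:`datetime.date`; JSON serialisation uses ISO 8601.
Character spans are 0-based half-open throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date as Date


class Category(str, enum.Enum):
    """Concept category of a detected mention or stored occurrence."""

    TUMOR_LOCATION = "TUMOR_LOCATION"
    MORPHOLOGY = "MORPHOLOGY"
    METASTASIS = "METASTASIS"
    RELAPSE = "RELAPSE"
    TREATMENT = "TREATMENT"
    TREATMENT_RESPONSE = "TREATMENT_RESPONSE"
    BIOMARKER = "BIOMARKER"
    UNKNOWN_PRIMARY_KEYWORD = "UNKNOWN_PRIMARY_KEYWORD"
    DATE = "DATE"


class Context(str, enum.Enum):
    """Assertion status of a mention in its textual context."""

    AFFIRMED = "AFFIRMED"
    NEGATED = "NEGATED"
    HYPOTHETICAL = "HYPOTHETICAL"


class CodeSystem(str, enum.Enum):
    ICD10 = "ICD10"
    ICDO3_TOPO = "ICDO3_TOPO"
    ICDO3_MORPHO = "ICDO3_MORPHO"
    CCAM = "CCAM"
    NONE = "NONE"


class DateOrigin(str, enum.Enum):
    """How an occurrence got its date: from the text, or the document date."""

    CONCEPT_LINKED = "CONCEPT_LINKED"
    DOCUMENT = "DOCUMENT"


class SourceKind(str, enum.Enum):
    REPORT = "REPORT"
    PMSI = "PMSI"


class DocType(str, enum.Enum):
    CONSULTATION = "CONSULTATION"
    HOSPITALISATION = "HOSPITALISATION"
    PATHOLOGY = "PATHOLOGY"


class TreatmentType(str, enum.Enum):
    SURGERY = "SURGERY"
    CHEMO = "CHEMO"
    RADIO = "RADIO"
    IMMUNO = "IMMUNO"


class ResponseKind(str, enum.Enum):
    COMPLETE = "COMPLETE"
    PARTIAL = "PARTIAL"
    PROGRESSION = "PROGRESSION"


class EventKind(str, enum.Enum):
    PRIMARY = "PRIMARY"
    LOCAL_RELAPSE = "LOCAL_RELAPSE"
    METASTATIC_RELAPSE = "METASTATIC_RELAPSE"


#: Sentinel topography for a cancer whose primary site was never identified.
UNKNOWN_PRIMARY = "UNKNOWN_PRIMARY"


# ---------------------------------------------------------------------------
# ground truth / synthetic corpus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Treatment:
    """One treatment course in a patient's ground-truth disease course.

    ``sessions`` only matters for session-based modalities (chemotherapy):
    it drives the number of coded hospital stays the discharge generator
    emits for this course.
    """

    type: TreatmentType
    start: Date
    response: ResponseKind | None = None
    sessions: int = 1


@dataclass(frozen=True)
class DiseaseCourse:
    """Ground-truth oncology timeline of one synthetic patient."""

    patient_id: str
    sex: str  # "F" | "M"
    birth_year: int
    primary_site: str  # ICD-O-3 topography code or UNKNOWN_PRIMARY
    morphology: str  # ICD-O-3 morphology code
    diagnosis_date: Date
    metastatic_onset: Date | None
    is_cup: bool
    treatments: tuple[Treatment, ...] = ()

    def validate(self) -> None:
        if self.metastatic_onset is not None and self.metastatic_onset < self.diagnosis_date:
            raise ValueError("metastatic_onset precedes diagnosis_date")
        if self.is_cup:
            if self.primary_site != UNKNOWN_PRIMARY:
                raise ValueError("CUP course must have UNKNOWN_PRIMARY site")
            if self.metastatic_onset != self.diagnosis_date:
                raise ValueError("CUP is metastatic at diagnosis by definition")
        for t in self.treatments:
            if t.start < self.diagnosis_date:
                raise ValueError("treatment starts before diagnosis")


@dataclass(frozen=True)
class GoldMention:
    """Gold annotation: what a perfect extractor should find in a document."""

    start: int
    end: int
    category: Category
    context: Context
    linked_date: Date | None = None
    code: str | None = None


@dataclass(frozen=True)
class SyntheticDocument:
    doc_id: str
    patient_id: str
    doc_date: Date
    doc_type: DocType
    text: str
    gold_mentions: tuple[GoldMention, ...] = ()

    def validate(self) -> None:
        n = len(self.text)
        for g in self.gold_mentions:
            if not (0 <= g.start < g.end <= n):
                raise ValueError(f"gold span ({g.start},{g.end}) outside text bounds")


# ---------------------------------------------------------------------------
# text processing output
# ---------------------------------------------------------------------------

@dataclass
class ConceptMention:
    """One detected concept, with character span into the processed text."""

    doc_id: str
    start: int
    end: int
    category: Category
    code: str | None = None
    context: Context = Context.AFFIRMED
    linked_date: Date | None = None
    related_to: int | None = None  # index of a sibling mention in the document


@dataclass
class StructuredDocument:
    doc_id: str
    patient_id: str
    doc_date: Date
    mentions: list[ConceptMention]
    redacted_text: str

    def validate(self) -> None:
        for m in self.mentions:
            if m.doc_id != self.doc_id:
                raise ValueError("mention doc_id mismatch")
            if not (0 <= m.start < m.end <= len(self.redacted_text)):
                raise ValueError("mention span outside document")


# ---------------------------------------------------------------------------
# elementary (pivot) model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConceptOccurrence:
    """One dated concept with provenance — the atom of the elementary model."""

    occurrence_id: str
    patient_id: str
    category: Category
    code: str | None
    context: Context
    date: Date
    date_origin: DateOrigin
    source: SourceKind
    source_id: str
    recorded_at: Date
    corroborated: bool = False

    def identity(self) -> tuple:
        """Content identity used for set semantics in the store."""
        return (
            self.patient_id, self.category, self.code, self.context,
            self.date, self.date_origin, self.source, self.source_id,
            self.occurrence_id,
        )


@dataclass(frozen=True)
class DischargeRecord:
    """One coded hospital stay (PMSI-like): diagnoses + procedure acts."""

    stay_id: str
    patient_id: str
    admission_date: Date
    discharge_date: Date
    main_dx_icd10: str
    associated_dx_icd10: tuple[str, ...] = ()
    acts_ccam: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.admission_date > self.discharge_date:
            raise ValueError("admission after discharge")


# ---------------------------------------------------------------------------
# inferred model
# ---------------------------------------------------------------------------

@dataclass
class TumorEvent:
    kind: EventKind
    date: Date
    supporting_ids: list[str] = field(default_factory=list)


@dataclass
class Cancer:
    primary_site: str
    morphology: str | None
    diagnosis_date: Date
    tumor_events: list[TumorEvent] = field(default_factory=list)


@dataclass
class ActRecord:
    type: str
    date: Date
    corroborated: bool = False
    supporting_ids: list[str] = field(default_factory=list)


@dataclass
class PatientProfile:
    patient_id: str
    cancers: list[Cancer] = field(default_factory=list)
    acts: list[ActRecord] = field(default_factory=list)
    document_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for c in self.cancers:
            dates = [e.date for e in c.tumor_events]
            if dates != sorted(dates):
                raise ValueError("tumor events not sorted by date")
            for e in c.tumor_events:
                if e.kind is EventKind.PRIMARY and e.date != c.diagnosis_date:
                    raise ValueError("PRIMARY event date must equal diagnosis_date")
                if e.kind is EventKind.METASTATIC_RELAPSE and e.date < c.diagnosis_date:
                    raise ValueError("metastatic relapse before diagnosis")


@dataclass(frozen=True)
class WindowDiagnostic:
    """One evaluated candidate window of the onset heuristic."""

    start: Date
    total_weight: float
    accepted: bool


@dataclass
class OnsetDiagnostics:
    windows: list[WindowDiagnostic] = field(default_factory=list)
    chosen_onset: Date | None = None
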