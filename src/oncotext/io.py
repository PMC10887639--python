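"""JSONL / CSV serialization with stable field order.

Every writer emits keys in a fixed order and UTF-8 with ``\\n`` line
endings, so that identical in-memory objects always serialize to
byte-identical files (the determinism contract of the whole pipeline).
"""

from __future__ import annotations

import json
from datetime import date as Date
from pathlib import Path
from typing import Any, Iterable, Iterator

from .types import (
    Category,
    ConceptMention,
    ConceptOccurrence,
    Context,
    DateOrigin,
    DischargeRecord,
    DocType,
    GoldMention,
    PatientProfile,
    SourceKind,
    StructuredDocument,
    SyntheticDocument,
)


def _iso(d: Date | None) -> str | None:
    return d.isoformat() if d is not None else None


def write_jsonl(path: str | Path, rows: Iterable[dict]) -> None:
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False))
                fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def read_jsonl(path: str | Path) -> Iterator[dict]:
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield json.loads(line)
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc


# -- documents --------------------------------------------------------------

def document_to_dict(d: SyntheticDocument) -> dict:
    return {
        "doc_id": d.doc_id,
        "patient_id": d.patient_id,
        "doc_date": _iso(d.doc_date),
        "doc_type": d.doc_type.value,
        "text": d.text,
    }


def gold_to_dict(d: SyntheticDocument) -> dict:
    return {
        "doc_id": d.doc_id,
        "mentions": [
            {
                "start": g.start,
                "end": g.end,
                "category": g.category.value,
                "context": g.context.value,
                "linked_date": _iso(g.linked_date),
                "code": g.code,
            }
            for g in d.gold_mentions
        ],
    }


def document_from_dict(row: dict, gold: dict | None = None) -> SyntheticDocument:
    mentions: tuple[GoldMention, ...] = ()
    if gold is not None:
        mentions = tuple(
            GoldMention(
                m["start"], m["end"], Category(m["category"]), Context(m["context"]),
                Date.fromisoformat(m["linked_date"]) if m["linked_date"] else None,
                m.get("code"),
            )
            for m in gold["mentions"]
        )
    return SyntheticDocument(
        row["doc_id"], row["patient_id"], Date.fromisoformat(row["doc_date"]),
        DocType(row["doc_type"]), row["text"], mentions,
    )


# -- discharge records ------------------------------------------------------

def discharge_to_dict(r: DischargeRecord) -> dict:
    return {
        "stay_id": r.stay_id,
        "patient_id": r.patient_id,
        "admission_date": _iso(r.admission_date),
        "discharge_date": _iso(r.discharge_date),
        "main_dx_icd10": r.main_dx_icd10,
        "associated_dx_icd10": list(r.associated_dx_icd10),
        "acts_ccam": list(r.acts_ccam),
    }


def discharge_from_dict(row: dict) -> DischargeRecord:
    return DischargeRecord(
        row["stay_id"], row["patient_id"],
        Date.fromisoformat(row["admission_date"]),
        Date.fromisoformat(row["discharge_date"]),
        row["main_dx_icd10"],
        tuple(row.get("associated_dx_icd10", [])),
        tuple(row.get("acts_ccam", [])),
    )


# -- structured documents ---------------------------------------------------

def structured_to_dict(sd: StructuredDocument) -> dict:
    return {
        "doc_id": sd.doc_id,
        "patient_id": sd.patient_id,
        "doc_date": _iso(sd.doc_date),
        "redacted_text": sd.redacted_text,
        "mentions": [
            {
                "start": m.start,
                "end": m.end,
                "category": m.category.value,
                "code": m.code,
                "context": m.context.value,
                "linked_date": _iso(m.linked_date),
                "related_to": m.related_to,
            }
            for m in sd.mentions
        ],
    }


def structured_from_dict(row: dict) -> StructuredDocument:
    mentions = [
        ConceptMention(
            row["doc_id"], m["start"], m["end"], Category(m["category"]),
            m.get("code"), Context(m["context"]),
            Date.fromisoformat(m["linked_date"]) if m.get("linked_date") else None,
            m.get("related_to"),
        )
        for m in row["mentions"]
    ]
    return StructuredDocument(
        row["doc_id"], row["patient_id"], Date.fromisoformat(row["doc_date"]),
        mentions, row["redacted_text"],
    )


# -- occurrences ------------------------------------------------------------

def occurrence_to_dict(o: ConceptOccurrence) -> dict:
    return {
        "occurrence_id": o.occurrence_id,
        "patient_id": o.patient_id,
        "category": o.category.value,
        "code": o.code,
        "context": o.context.value,
        "date": _iso(o.date),
        "date_origin": o.date_origin.value,
        "source": o.source.value,
        "source_id": o.source_id,
        "recorded_at": _iso(o.recorded_at),
        "corroborated": o.corroborated,
    }


def occurrence_from_dict(row: dict) -> ConceptOccurrence:
    return ConceptOccurrence(
        row["occurrence_id"], row["patient_id"], Category(row["category"]),
        row.get("code"), Context(row["context"]),
        Date.fromisoformat(row["date"]), DateOrigin(row["date_origin"]),
        SourceKind(row["source"]), row["source_id"],
        Date.fromisoformat(row["recorded_at"]), bool(row.get("corroborated", False)),
    )


# -- profiles ---------------------------------------------------------------

def profile_to_dict(p: PatientProfile) -> dict:
    return {
        "patient_id": p.patient_id,
        "cancers": [
            {
                "primary_site": c.primary_site,
                "morphology": c.morphology,
                "diagnosis_date": _iso(c.diagnosis_date),
                "tumor_events": [
                    {
                        "kind": e.kind.value,
                        "date": _iso(e.date),
                        "supporting_ids": list(e.supporting_ids),
                    }
                    for e in c.tumor_events
                ],
            }
            for c in p.cancers
        ],
        "acts": [
            {
                "type": a.type,
                "date": _iso(a.date),
                "corroborated": a.corroborated,
                "supporting_ids": list(a.supporting_ids),
            }
            for a in p.acts
        ],
        "document_ids": list(p.document_ids),
    }


def profile_from_dict(row: dict) -> PatientProfile:
    from .types import ActRecord, Cancer, EventKind, TumorEvent

    return PatientProfile(
        row["patient_id"],
        [
            Cancer(
                c["primary_site"], c.get("morphology"),
                Date.fromisoformat(c["diagnosis_date"]),
                [
                    TumorEvent(EventKind(e["kind"]), Date.fromisoformat(e["date"]),
                               list(e.get("supporting_ids", [])))
                    for e in c["tumor_events"]
                ],
            )
            for c in row["cancers"]
        ],
        [
            ActRecord(a["type"], Date.fromisoformat(a["date"]),
                      bool(a.get("corroborated", False)),
                      list(a.get("supporting_ids", [])))
            for a in row["acts"]
        ],
        list(row.get("document_ids", [])),
    )


def write_json(path: str | Path, obj: Any) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, ensure_ascii=False, indent=2)
        fh.write("\n")
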