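"""End-to-end orchestration: documents + discharge records -> profiles.

Thin glue over the stage modules, used by the command-line interface,
the federated query layer (which rebuilds centre stores in-process) and
the evaluation experiments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .config import OnsetParams
from .lexicon import Lexicon
from .io import (
    discharge_from_dict,
    profile_from_dict,
    read_jsonl,
    structured_from_dict,
)
from .store import PivotStore
from .structuring import build_profile_with_diagnostics
from .terminology import default_lexicon
from .textproc import process_document
from .types import DischargeRecord, OnsetDiagnostics, PatientProfile


def build_store(document_records: Iterable[dict],
                discharges: Iterable[DischargeRecord],
                lex: Lexicon) -> PivotStore:
    """Process raw document records and ingest everything into a store."""
    store = PivotStore()
    for rec in document_records:
        store.ingest_document(process_document(rec, lex))
    for r in discharges:
        store.ingest_discharge(r)
    return store


def build_profiles(store: PivotStore, params: OnsetParams,
                   ) -> dict[str, tuple[PatientProfile, OnsetDiagnostics]]:
    out: dict[str, tuple[PatientProfile, OnsetDiagnostics]] = {}
    for pid in store.patients():
        occ = store.occurrences_for_patient(pid)
        out[pid] = build_profile_with_diagnostics(occ, params)
    return out


def process_centre_dir(centre_dir: str | Path,
                       lex: Lexicon | None = None,
                       params: OnsetParams | None = None,
                       ) -> tuple[dict[str, PatientProfile], dict[str, list[str]]]:
    """Load one centre directory into (profiles by patient, texts by patient).

    Uses ``profiles.jsonl`` when the structuring stage already ran there,
    otherwise recomputes profiles from ``documents.jsonl`` + ``pmsi.jsonl``.
    """
    centre_dir = Path(centre_dir)
    lex = lex or default_lexicon()
    params = params or OnsetParams()

    texts: dict[str, list[str]] = {}
    doc_records = list(read_jsonl(centre_dir / "documents.jsonl"))
    for rec in doc_records:
        texts.setdefault(rec["patient_id"], []).append(rec["text"])

    profiles_path = centre_dir / "profiles.jsonl"
    if profiles_path.exists():
        profiles = {row["patient_id"]: profile_from_dict(row)
                    for row in read_jsonl(profiles_path)}
    else:
        pmsi_path = centre_dir / "pmsi.jsonl"
        discharges = ([discharge_from_dict(r) for r in read_jsonl(pmsi_path)]
                      if pmsi_path.exists() else [])
        store = build_store(doc_records, discharges, lex)
        profiles = {pid: prof for pid, (prof, _) in build_profiles(store, params).items()}
    return profiles, texts


def structured_records_to_store(structured_rows: Iterable[dict],
                                discharges: Iterable[DischargeRecord]) -> PivotStore:
    """Ingest already-processed structured documents (JSONL rows)."""
    store = PivotStore()
    for row in structured_rows:
        store.ingest_document(structured_from_dict(row))
    for r in discharges:
        store.ingest_discharge(r)
    return store
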