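"""Syntactic validation and semantics of ICD-10 / CCAM codes.

Only the small slices of the classifications that the pipeline reasons
about are encoded here: the secondary-malignancy block (C77–C79), the
session-encounter codes (Z51.0 radiotherapy, Z51.1 chemotherapy) and the
act-type compatibility used when corroborating report mentions against
coded discharge stays.
"""

from __future__ import annotations

import re

from .types import TreatmentType

ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")
CCAM_RE = re.compile(r"^[A-Z]{4}\d{3}$")

#: ICD-10 block for secondary malignant neoplasms (metastases).
_SECONDARY_PREFIXES = ("C77", "C78", "C79")

#: encounter code for a chemotherapy session; systemic immunotherapy is
#: administered in the same kind of coded session stay.
CHEMO_SESSION_CODE = "Z51.1"
RADIO_SESSION_CODE = "Z51.0"


def is_valid_icd10(code: str) -> bool:
    return bool(ICD10_RE.match(code))


def is_valid_ccam(code: str) -> bool:
    return bool(CCAM_RE.match(code))


def is_secondary_malignancy(code: str) -> bool:
    """True for codes in the C77–C79 secondary-malignancy block."""
    return code[:3] in _SECONDARY_PREFIXES


def is_primary_malignancy(code: str) -> bool:
    return code.startswith("C") and not is_secondary_malignancy(code)


def prefix3(code: str) -> str:
    """Three-character ICD-10 category, the granularity of corroboration."""
    return code[:3]


def act_types_for(code: str) -> frozenset[TreatmentType]:
    """Treatment types a coded act/encounter is compatible with."""
    if code == CHEMO_SESSION_CODE:
        return frozenset({TreatmentType.CHEMO, TreatmentType.IMMUNO})
    if code == RADIO_SESSION_CODE:
        return frozenset({TreatmentType.RADIO})
    if CCAM_RE.match(code):
        return frozenset({TreatmentType.SURGERY})
    return frozenset()
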