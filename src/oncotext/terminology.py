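"""Built-in French oncology terminology and the default lexicon.

The tables below are a deliberately small, closed vocabulary: enough to
cover primary sites, morphologies, metastasis/relapse wording, treatment
modalities, responses, a couple of biomarkers, and the ten phrases by
which cancers of unknown primary (CUP) are referred to in French records.
Each table carries both the surface form(s) used when rendering synthetic
reports and the code attached on detection.
"""

from __future__ import annotations

from .lexicon import Lexicon
from .types import Category, CodeSystem, TreatmentType

#: (display form, ICD-O-3 topography / ICD-10 site code)
SITES: list[tuple[str, str]] = [
    ("sein", "C50.9"),
    ("poumon", "C34.9"),
    ("côlon", "C18.9"),
    ("prostate", "C61.9"),
    ("pancréas", "C25.9"),
    ("ovaire", "C56.9"),
    ("estomac", "C16.9"),
    ("rein", "C64.9"),
]

#: (display form, ICD-O-3 morphology code)
MORPHOLOGIES: list[tuple[str, str]] = [
    ("adénocarcinome", "8140/3"),
    ("carcinome épidermoïde", "8070/3"),
    ("carcinome canalaire infiltrant", "8500/3"),
]

#: (display form, treatment type)
TREATMENTS: list[tuple[str, TreatmentType]] = [
    ("chimiothérapie", TreatmentType.CHEMO),
    ("radiothérapie", TreatmentType.RADIO),
    ("immunothérapie", TreatmentType.IMMUNO),
    ("chirurgie", TreatmentType.SURGERY),
]

RESPONSES: list[tuple[str, str]] = [
    ("réponse complète", "COMPLETE"),
    ("réponse partielle", "PARTIAL"),
    ("progression", "PROGRESSION"),
]

BIOMARKERS: list[str] = ["her2", "msi"]

#: the ten phrases of the refined unknown-primary keyword list; the mix of
#: accented and unaccented spellings is intentional (records contain both)
#: and forces accent-insensitive matching.
CUP_KEYWORDS: list[str] = [
    "ACUP",
    "primitif inconnu",
    "de primitif inconnu",
    "sans primitif retrouve",
    "sans primitif connu",
    "d’origine indéterminée",
    "pas de primitif retrouve",
    "d’origine inconnue",
    "recherche de la tumeur primitive",
    "autre primitif",
]

#: relapse wording; the code distinguishes local from distant relapse,
#: which decides whether the occurrence is a metastasis-onset candidate.
RELAPSE_TERMS: list[tuple[str, str | None]] = [
    ("récidive", None),
    ("récidive locale", "LOCAL"),
    ("récidive à distance", "DISTANT"),
]

METASTASIS_TERMS: list[str] = ["métastase"]

#: ICD-10 code for malignant neoplasm without specification of site,
#: the coded counterpart of an unidentified primary.
CUP_ICD10 = "C80.9"

#: secondary-malignancy codes the discharge generator draws from.
METASTASIS_ICD10 = ["C78.0", "C78.7", "C79.5"]

#: CCAM act used for surgical stays (format-valid placeholder act).
SURGERY_CCAM = "HHFA001"


SITE_BY_CODE = {code: term for term, code in SITES}
MORPH_BY_CODE = {code: term for term, code in MORPHOLOGIES}
TREATMENT_TERM = {ttype: term for term, ttype in TREATMENTS}
RESPONSE_TERM = {code: term for term, code in RESPONSES}


def site_code(term: str) -> str:
    for t, code in SITES:
        if t == term:
            return code
    raise KeyError(term)


def default_lexicon() -> Lexicon:
    """Assemble the built-in lexicon from the terminology tables."""
    lex = Lexicon()
    for term, code in SITES:
        lex.add(term, Category.TUMOR_LOCATION, code, CodeSystem.ICDO3_TOPO)
    for term, code in MORPHOLOGIES:
        lex.add(term, Category.MORPHOLOGY, code, CodeSystem.ICDO3_MORPHO)
    for term in METASTASIS_TERMS:
        lex.add(term, Category.METASTASIS, None, CodeSystem.NONE)
    for term, code in RELAPSE_TERMS:
        lex.add(term, Category.RELAPSE, code, CodeSystem.NONE)
    for term, ttype in TREATMENTS:
        lex.add(term, Category.TREATMENT, ttype.value, CodeSystem.NONE)
    for term, code in RESPONSES:
        lex.add(term, Category.TREATMENT_RESPONSE, code, CodeSystem.NONE)
    for term in BIOMARKERS:
        lex.add(term, Category.BIOMARKER, None, CodeSystem.NONE)
    for term in CUP_KEYWORDS:
        lex.add(term, Category.UNKNOWN_PRIMARY_KEYWORD, None, CodeSystem.NONE)
    return lex
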