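"""Ground-truthed synthetic corpus generation.

Every downstream stage is tested against corpora produced here: each
patient gets a ground-truth :class:`~oncotext.types.DiseaseCourse`, a set
of French-like medical reports rendered from templates (with character-
exact gold annotations), and coded hospital-discharge records.

The generator emulates the awkward properties of real report streams:

* a history section repeated verbatim across a patient's reports,
* negated ("pas de métastase") and hypothetical ("suspicion de
  métastase") mentions injected at configurable rates,
* concept-linked date phrases vs. document-date fallback,
* unknown-primary phrasing drawn from the ten-keyword CUP list, at a
  prevalence below 5% of patients.

Determinism: every random draw flows from ``(config.seed, patient index,
stream)`` seed sequences, so the same config regenerates a byte-identical
corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .codes import CHEMO_SESSION_CODE, RADIO_SESSION_CODE, is_secondary_malignancy
from .config import CorpusConfig
from .io import discharge_to_dict, document_to_dict, gold_to_dict, write_jsonl
from .dates import format_date_fr
from .terminology import (
    CUP_ICD10,
    CUP_KEYWORDS,
    METASTASIS_ICD10,
    MORPHOLOGIES,
    MORPH_BY_CODE,
    RESPONSE_TERM,
    SITES,
    SITE_BY_CODE,
    SURGERY_CCAM,
    TREATMENT_TERM,
    default_lexicon,
)
from .types import (
    UNKNOWN_PRIMARY,
    Category,
    Context,
    DischargeRecord,
    DiseaseCourse,
    DocType,
    GoldMention,
    ResponseKind,
    SyntheticDocument,
    Treatment,
    TreatmentType,
)

_EPOCH_START = Date(2010, 1, 1)
_EPOCH_END = Date(2022, 12, 31)

#: adjectives used to flavour metastasis wording (not lexicon terms).
_MET_ADJ_PLURAL = ["osseuses", "hépatiques", "pulmonaires"]
_MET_ADJ_SING = ["osseuse", "hépatique", "pulmonaire"]

#: carrier sentences for each CUP keyword; chosen so the keyword is the
#: only (and longest) lexicon match and no context trigger precedes it.
_CUP_WRAPPERS = {
    "ACUP": "Conclusion : {kw}.",
    "primitif inconnu": "Tumeur maligne, {kw}.",
    "de primitif inconnu": "Carcinome {kw}.",
    "sans primitif retrouve": "Maladie métastatique {kw}.",
    "sans primitif connu": "Atteinte secondaire {kw}.",
    "d’origine indéterminée": "Carcinome {kw}.",
    "pas de primitif retrouve": "Bilan : {kw}.",
    "d’origine inconnue": "Tumeur maligne {kw}.",
    "recherche de la tumeur primitive": "Poursuite de la {kw}.",
    "autre primitif": "Orientation vers un {kw}.",
}


def _rand_date(rng: np.random.Generator, lo: Date, hi: Date) -> Date:
    return lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


# ---------------------------------------------------------------------------
# disease courses
# ---------------------------------------------------------------------------

def generate_course(config: CorpusConfig, draw_index: int) -> DiseaseCourse:
    """Draw one ground-truth disease course, deterministic in (seed, index)."""
    if draw_index >= config.n_patients:
        raise ValueError(f"draw_index {draw_index} >= n_patients {config.n_patients}")
    rng = np.random.default_rng([config.seed, draw_index, 0])
    patient_id = f"P{draw_index:05d}"
    sex = "F" if rng.random() < 0.5 else "M"
    birth_year = int(rng.integers(1935, 1986))
    diagnosis = _rand_date(rng, _EPOCH_START, _EPOCH_END)
    morphology = MORPHOLOGIES[int(rng.integers(len(MORPHOLOGIES)))][1]

    is_cup = bool(rng.random() < config.cup_prevalence)
    if is_cup:
        site = UNKNOWN_PRIMARY
        onset: Date | None = diagnosis
    else:
        site = SITES[int(rng.integers(len(SITES)))][1]
        if rng.random() < config.metastatic_fraction:
            # one in five metastatic cancers presents de novo metastatic
            onset = diagnosis if rng.random() < 0.2 else (
                diagnosis + timedelta(days=int(rng.integers(60, 1096)))
            )
        else:
            onset = None

    treatments: list[Treatment] = []
    if not is_cup and rng.random() < 0.6:
        treatments.append(Treatment(
            TreatmentType.SURGERY, diagnosis + timedelta(days=int(rng.integers(14, 61)))
        ))
    if rng.random() < 0.7:
        resp = [None, ResponseKind.COMPLETE, ResponseKind.PARTIAL][int(rng.integers(3))]
        treatments.append(Treatment(
            TreatmentType.CHEMO, diagnosis + timedelta(days=int(rng.integers(21, 91))),
            resp, sessions=int(rng.integers(3, 7)),
        ))
    if onset is not None:
        # a new systemic line opens shortly after metastatic progression
        resp = ResponseKind.PROGRESSION if rng.random() < 0.4 else ResponseKind.PARTIAL
        treatments.append(Treatment(
            TreatmentType.CHEMO, onset + timedelta(days=int(rng.integers(0, 31))),
            resp, sessions=int(rng.integers(3, 7)),
        ))
    elif rng.random() < 0.3:
        treatments.append(Treatment(
            TreatmentType.RADIO, diagnosis + timedelta(days=int(rng.integers(30, 121))),
            None, sessions=int(rng.integers(5, 11)),
        ))

    course = DiseaseCourse(
        patient_id, sex, birth_year, site, morphology, diagnosis, onset, is_cup,
        tuple(sorted(treatments, key=lambda t: (t.start, t.type.value))),
    )
    course.validate()
    return course


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

class _DocBuilder:
    """Accumulates text parts while recording gold spans."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0
        self.gold: list[GoldMention] = []

    def text(self, s: str) -> None:
        self.parts.append(s)
        self.pos += len(s)

    def term(self, surface: str, category: Category, *,
             context: Context = Context.AFFIRMED,
             code: str | None = None, linked_date: Date | None = None) -> None:
        self.gold.append(GoldMention(self.pos, self.pos + len(surface),
                                     category, context, linked_date, code))
        self.text(surface)

    def splice(self, fragment: tuple[str, tuple[GoldMention, ...]]) -> None:
        txt, gold = fragment
        for g in gold:
            self.gold.append(GoldMention(g.start + self.pos, g.end + self.pos,
                                         g.category, g.context, g.linked_date, g.code))
        self.text(txt)

    def fragment(self) -> tuple[str, tuple[GoldMention, ...]]:
        return "".join(self.parts), tuple(self.gold)


#: CUP keywords that read naturally after "carcinome" in a history line;
#: only a subset contains the literal base-query phrase "primitif inconnu",
#: so single-keyword searches genuinely miss some patients.
_HISTORY_CUP_KEYWORDS = [
    "de primitif inconnu",
    "d’origine indéterminée",
    "d’origine inconnue",
    "sans primitif retrouve",
    "sans primitif connu",
]


def _history_fragment(course: DiseaseCourse, date_style: str,
                      cup_kw: str = "de primitif inconnu") -> tuple[str, tuple[GoldMention, ...]]:
    """The rarely-updated history section, reused verbatim across reports."""
    b = _DocBuilder()
    b.text("Antécédents : ")
    if course.is_cup:
        b.text("carcinome ")
        b.term(cup_kw, Category.UNKNOWN_PRIMARY_KEYWORD,
               linked_date=course.diagnosis_date)
    else:
        b.term(MORPH_BY_CODE[course.morphology], Category.MORPHOLOGY,
               code=course.morphology, linked_date=course.diagnosis_date)
        b.text(", ")
        b.term(SITE_BY_CODE[course.primary_site], Category.TUMOR_LOCATION,
               code=course.primary_site, linked_date=course.diagnosis_date)
    b.text(" diagnostiqué le ")
    b.text(format_date_fr(course.diagnosis_date, date_style))
    b.text(".")
    return b.fragment()


def _date_style(rng: np.random.Generator) -> str:
    return "long" if rng.random() < 0.5 else "numeric"


def render_documents(course: DiseaseCourse, config: CorpusConfig,
                     rng: np.random.Generator | None = None) -> list[SyntheticDocument]:
    """Render a patient's chronological report stream with gold annotations."""
    course.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, int(course.patient_id[1:]), 1])

    lo, hi = config.reports_per_patient
    n_docs = int(rng.integers(lo, hi + 1))
    diag, onset = course.diagnosis_date, course.metastatic_onset

    end = diag + timedelta(days=730)
    if onset is not None:
        end = max(end, onset + timedelta(days=365))
    for t in course.treatments:
        end = max(end, t.start + timedelta(days=180))

    dates = [diag + timedelta(days=int(rng.integers(0, 15)))]
    if onset is not None:
        dates.append(onset + timedelta(days=int(rng.integers(0, 15))))
    while len(dates) < n_docs:
        dates.append(_rand_date(rng, diag, end))
    dates.sort()

    cup_kw = _HISTORY_CUP_KEYWORDS[int(rng.integers(len(_HISTORY_CUP_KEYWORDS)))]
    history = _history_fragment(course, _date_style(rng), cup_kw)
    onset_doc_idx = None
    if onset is not None:
        onset_doc_idx = next(i for i, d in enumerate(dates) if d >= onset)

    # assign treatment announcements / responses to documents
    announce: dict[int, list[Treatment]] = {}
    respond: dict[int, list[Treatment]] = {}
    for t in course.treatments:
        idx = next((i for i, d in enumerate(dates) if d >= t.start), len(dates) - 1)
        announce.setdefault(idx, []).append(t)
        if t.response is not None:
            ridx = next((i for i, d in enumerate(dates)
                         if d >= t.start + timedelta(days=90)), None)
            if ridx is not None:
                respond.setdefault(ridx, []).append(t)

    docs: list[SyntheticDocument] = []
    for k, doc_date in enumerate(dates):
        doc_type = DocType.CONSULTATION if k == 0 else DocType(
            str(rng.choice(["CONSULTATION", "HOSPITALISATION", "PATHOLOGY"],
                           p=[0.6, 0.25, 0.15]))
        )
        b = _DocBuilder()
        header = {"CONSULTATION": "consultation", "HOSPITALISATION": "hospitalisation",
                  "PATHOLOGY": "anatomopathologie"}[doc_type.value]
        b.text(f"Compte rendu de {header} du {format_date_fr(doc_date, 'numeric')}.")

        if k == 0 or rng.random() < config.history_redundancy_prob:
            b.text(" ")
            b.splice(history)

        for t in announce.get(k, ()):
            b.text(" Début de ")
            if rng.random() < config.explicit_date_rate:
                b.term(TREATMENT_TERM[t.type], Category.TREATMENT,
                       code=t.type.value, linked_date=t.start)
                b.text(" le " + format_date_fr(t.start, _date_style(rng)) + ".")
            else:
                b.term(TREATMENT_TERM[t.type], Category.TREATMENT, code=t.type.value)
                b.text(".")

        for t in respond.get(k, ()):
            surface = RESPONSE_TERM[t.response.value]
            b.text(" ")
            b.term(surface[0].upper() + surface[1:], Category.TREATMENT_RESPONSE,
                   code=t.response.value)
            b.text(" après ")
            b.term(TREATMENT_TERM[t.type], Category.TREATMENT, code=t.type.value)
            b.text(".")

        if onset is not None and doc_date >= onset:
            if k == onset_doc_idx or rng.random() < 0.8:
                a = int(rng.integers(len(_MET_ADJ_PLURAL)))
                explicit = rng.random() < config.explicit_date_rate
                as_relapse = rng.random() < 0.25
                b.text(" ")
                if as_relapse:
                    b.term("Récidive à distance", Category.RELAPSE, code="DISTANT",
                           linked_date=onset if explicit else None)
                    b.text(" le " + format_date_fr(onset, _date_style(rng)) + "."
                           if explicit else ".")
                elif explicit:
                    b.term("Métastases", Category.METASTASIS, linked_date=onset)
                    b.text(f" {_MET_ADJ_PLURAL[a]} diagnostiquées le "
                           + format_date_fr(onset, _date_style(rng)) + ".")
                else:
                    b.text("Présence de ")
                    b.term("métastases", Category.METASTASIS)
                    b.text(f" {_MET_ADJ_PLURAL[a]}.")

        if course.is_cup and (k == 0 or rng.random() < 0.8):
            kw = CUP_KEYWORDS[int(rng.integers(len(CUP_KEYWORDS)))]
            before, after = _CUP_WRAPPERS[kw].split("{kw}")
            b.text(" " + before)
            b.term(kw, Category.UNKNOWN_PRIMARY_KEYWORD)
            b.text(after)
        elif (not course.is_cup and onset == diag and k == 0
              and rng.random() < 0.3):
            # diagnostic-uncertainty phrasing in de novo metastatic work-ups:
            # the primary is eventually identified, but early reports carry
            # unknown-primary wording (a realistic query false positive)
            b.text(" Poursuite de la ")
            b.term("recherche de la tumeur primitive", Category.UNKNOWN_PRIMARY_KEYWORD)
            b.text(".")

        if rng.random() < config.negation_rate:
            b.text(" Pas de ")
            b.term("métastase", Category.METASTASIS, context=Context.NEGATED)
            b.text(" décelée.")
        if rng.random() < config.hypothesis_rate:
            a = int(rng.integers(len(_MET_ADJ_SING)))
            b.text(" Suspicion de ")
            b.term("métastase", Category.METASTASIS, context=Context.HYPOTHETICAL)
            b.text(f" {_MET_ADJ_SING[a]}.")

        if doc_type is DocType.PATHOLOGY and rng.random() < 0.5:
            b.text(" Statut ")
            b.term("HER2", Category.BIOMARKER)
            b.text(" positif.")

        b.text(" Poursuite de la surveillance." if rng.random() < 0.5
               else " Examen clinique satisfaisant.")

        text, gold = b.fragment()
        doc = SyntheticDocument(f"{course.patient_id}-D{k:02d}", course.patient_id,
                                doc_date, doc_type, text, gold)
        doc.validate()
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# discharge records
# ---------------------------------------------------------------------------

def generate_pmsi(course: DiseaseCourse) -> list[DischargeRecord]:
    """Coded hospital stays implied by the course; deterministic, no rng.

    Stays carry only stay dates and codes — no diagnosis date.  Session
    treatments (chemo/immuno, radiotherapy) yield one encounter-coded stay
    per session, without drug detail.  Once the course is metastatic, stays
    carry an associated secondary-malignancy code (C77–C79 block).
    """
    course.validate()
    onset = course.metastatic_onset
    site_icd = CUP_ICD10 if course.primary_site == UNKNOWN_PRIMARY else course.primary_site
    met_code = METASTASIS_ICD10[onset.toordinal() % len(METASTASIS_ICD10)] if onset else None

    def assoc(adm: Date, base: list[str]) -> tuple[str, ...]:
        extra = [met_code] if (onset is not None and adm >= onset) else []
        return tuple(base + extra)

    raw: list[tuple[Date, Date, str, tuple[str, ...], tuple[str, ...]]] = []
    for t in course.treatments:
        if t.type is TreatmentType.SURGERY:
            raw.append((t.start, t.start + timedelta(days=3), site_icd,
                        assoc(t.start, []), (SURGERY_CCAM,)))
        elif t.type in (TreatmentType.CHEMO, TreatmentType.IMMUNO):
            for s in range(t.sessions):
                adm = t.start + timedelta(days=21 * s)
                raw.append((adm, adm + timedelta(days=1), CHEMO_SESSION_CODE,
                            assoc(adm, [site_icd]), ()))
        elif t.type is TreatmentType.RADIO:
            for s in range(t.sessions):
                adm = t.start + timedelta(days=7 * s)
                raw.append((adm, adm + timedelta(days=1), RADIO_SESSION_CODE,
                            assoc(adm, [site_icd]), ()))

    if onset is not None:
        has_met = any(
            is_secondary_malignancy(c)
            for (_, _, main, ass, _) in raw for c in (main, *ass)
        )
        if not has_met:
            adm = onset + timedelta(days=7)
            raw.append((adm, adm + timedelta(days=2), site_icd, (met_code,), ()))

    raw.sort(key=lambda r: (r[0], r[2]))
    records = [
        DischargeRecord(f"{course.patient_id}-S{i:02d}", course.patient_id,
                        adm, dis, main, ass, acts)
        for i, (adm, dis, main, ass, acts) in enumerate(raw)
    ]
    for r in records:
        r.validate()
    return records


# ---------------------------------------------------------------------------
# whole-corpus assembly
# ---------------------------------------------------------------------------

@dataclass
class CentreData:
    centre_id: str
    documents: list[SyntheticDocument]
    discharges: list[DischargeRecord]


@dataclass
class CorpusBundle:
    config: CorpusConfig
    courses: list[DiseaseCourse]
    centres: list[CentreData]

    def centre_of(self, patient_id: str) -> str:
        idx = int(patient_id[1:])
        return self.centres[idx % len(self.centres)].centre_id

    def ground_truth(self) -> pd.DataFrame:
        rows = []
        for c in self.courses:
            rows.append({
                "patient_id": c.patient_id,
                "centre_id": self.centre_of(c.patient_id),
                "sex": c.sex,
                "birth_year": c.birth_year,
                "primary_site": c.primary_site,
                "morphology": c.morphology,
                "diagnosis_date": c.diagnosis_date.isoformat(),
                "metastatic_onset": c.metastatic_onset.isoformat() if c.metastatic_onset else "",
                "is_cup": c.is_cup,
                "n_treatments": len(c.treatments),
            })
        return pd.DataFrame(rows)


def generate_corpus(config: CorpusConfig, out_dir: str | Path | None = None) -> CorpusBundle:
    """Generate the full multi-centre corpus; optionally write artifacts.

    Patients are partitioned across centres round-robin by index (disjoint
    and balanced).  When ``out_dir`` is given, writes per-centre
    ``documents.jsonl`` / ``gold.jsonl`` / ``pmsi.jsonl`` plus top-level
    ``ground_truth.csv`` and ``lexicon.csv``.
    """
    centres = [CentreData(f"centre_{k + 1:02d}", [], []) for k in range(config.n_centres)]
    courses: list[DiseaseCourse] = []
    for i in range(config.n_patients):
        course = generate_course(config, i)
        courses.append(course)
        centre = centres[i % config.n_centres]
        centre.documents.extend(render_documents(course, config))
        centre.discharges.extend(generate_pmsi(course))
    bundle = CorpusBundle(config, courses, centres)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for centre in centres:
            cdir = out / centre.centre_id
            cdir.mkdir(exist_ok=True)
            write_jsonl(cdir / "documents.jsonl",
                        (document_to_dict(d) for d in centre.documents))
            write_jsonl(cdir / "gold.jsonl",
                        (gold_to_dict(d) for d in centre.documents))
            write_jsonl(cdir / "pmsi.jsonl",
                        (discharge_to_dict(r) for r in centre.discharges))
        bundle.ground_truth().to_csv(out / "ground_truth.csv", index=False,
                                     lineterminator="\n")
        default_lexicon().to_csv(out / "lexicon.csv")
    return bundle
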