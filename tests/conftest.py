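"""Shared fixtures: lexicon, small synthetic corpora, occurrence builders."""

from __future__ import annotations

from datetime import date as Date

import pytest

from oncotext.config import CorpusConfig, OnsetParams
from oncotext.io import document_to_dict
from oncotext.pipeline import build_profiles, build_store
from oncotext.synthesis import generate_corpus
from oncotext.terminology import default_lexicon
from oncotext.types import (
    Category,
    ConceptOccurrence,
    Context,
    DateOrigin,
    SourceKind,
)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_noisy_bundle():
    """Default-noise corpus, small enough for per-test use."""
    return generate_corpus(CorpusConfig(n_patients=80, seed=5))


@pytest.fixture(scope="session")
def small_clean_bundle():
    """Zero-noise corpus: no negated or hypothetical injections."""
    return generate_corpus(CorpusConfig(
        n_patients=60, negation_rate=0.0, hypothesis_rate=0.0,
        cup_prevalence=0.05, seed=11, n_centres=1,
    ))


@pytest.fixture(scope="session")
def noisy_profiles(small_noisy_bundle, lexicon):
    """(profiles+diagnostics by patient, bundle) for the noisy corpus."""
    out = {}
    for centre in small_noisy_bundle.centres:
        store = build_store((document_to_dict(d) for d in centre.documents),
                            centre.discharges, lexicon)
        out.update(build_profiles(store, OnsetParams()))
    return out


def make_occurrence(
    date: Date,
    *,
    patient_id: str = "P1",
    category: Category = Category.METASTASIS,
    code: str | None = None,
    context: Context = Context.AFFIRMED,
    origin: DateOrigin = DateOrigin.DOCUMENT,
    source: SourceKind = SourceKind.REPORT,
    source_id: str = "doc-1",
    occurrence_id: str | None = None,
    recorded_at: Date | None = None,
) -> ConceptOccurrence:
    return ConceptOccurrence(
        occurrence_id=occurrence_id or f"{source_id}:{date.isoformat()}",
        patient_id=patient_id,
        category=category,
        code=code,
        context=context,
        date=date,
        date_origin=origin,
        source=source,
        source_id=source_id,
        recorded_at=recorded_at or date,
    )
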