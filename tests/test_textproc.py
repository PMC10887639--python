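"""Concept detection, context classification, date and relation linking."""

from __future__ import annotations

from datetime import date as Date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncotext.lexicon import Lexicon
from oncotext.textnorm import NormalizedDoc, normalize_text
from oncotext.textproc import (
    attach_dates,
    classify_context,
    detect_dates,
    detect_mentions,
    process_document,
    redact_identifiers,
)
from oncotext.types import Category, Context

from .oracles import token_gap_oracle


def _doc(text: str, **kw) -> dict:
    base = {"doc_id": "d1", "patient_id": "p1", "doc_date": "2022-01-15",
            "text": text}
    base.update(kw)
    return base


# ---------------------------------------------------------------------------
# redaction
# ---------------------------------------------------------------------------

class TestRedaction:
    def test_clean_text_unchanged(self):
        t = "Examen clinique satisfaisant du 12/03/2020."
        assert redact_identifiers(t) == t

    def test_long_digit_run(self):
        assert redact_identifiers("N° dossier 1234567") == "N° dossier <ID>"

    def test_email_and_name(self):
        out = redact_identifiers("Contact: jean.d@hopital.fr, Dr Dupont")
        assert "<EMAIL>" in out and "Dr <NAME>" in out

    @settings(max_examples=100, deadline=None)
    @given(st.text(max_size=60))
    def test_idempotent(self, text):
        once = redact_identifiers(text)
        assert redact_identifiers(once) == once


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

class TestDetection:
    def test_no_terms_present(self, lexicon):
        doc = NormalizedDoc("Examen clinique satisfaisant.")
        assert detect_mentions(doc, lexicon, "d1") == []

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            detect_mentions(NormalizedDoc("x"), Lexicon(), "d1")

    def test_longest_match_wins(self, lexicon):
        """With both "primitif inconnu" and "de primitif inconnu" in the
        vocabulary, the longer phrase is the single match."""
        text = "carcinome de primitif inconnu"
        doc = NormalizedDoc(text)
        mentions = detect_mentions(doc, lexicon, "d1")
        assert len(mentions) == 1
        assert text[mentions[0].start:mentions[0].end] == "de primitif inconnu"
        assert mentions[0].category is Category.UNKNOWN_PRIMARY_KEYWORD

    def test_accent_and_case_insensitive(self, lexicon):
        doc = NormalizedDoc("MÉTASTASES au niveau du Côlon")
        cats = {m.category for m in detect_mentions(doc, lexicon, "d1")}
        assert cats == {Category.METASTASIS, Category.TUMOR_LOCATION}

    def test_spans_in_original_coordinates(self, lexicon):
        text = "Bilan :   carcinome   épidermoïde  du poumon"
        doc = NormalizedDoc(text)
        for m in detect_mentions(doc, lexicon, "d1"):
            norm_span, _ = normalize_text(text[m.start:m.end])
            assert norm_span in lexicon

    def test_determinism(self, lexicon):
        text = "métastase du sein, récidive à distance, chimiothérapie"
        a = detect_mentions(NormalizedDoc(text), lexicon, "d1")
        b = detect_mentions(NormalizedDoc(text), lexicon, "d1")
        assert a == b


# ---------------------------------------------------------------------------
# context
# ---------------------------------------------------------------------------

class TestContext:
    @pytest.mark.parametrize("text, expected", [
        ("métastase hépatique confirmée", Context.AFFIRMED),
        ("pas de métastase décelée", Context.NEGATED),
        ("absence de métastase", Context.NEGATED),
        ("aucune métastase visible", Context.NEGATED),
        ("suspicion de métastase osseuse", Context.HYPOTHETICAL),
        ("recherche de métastase", Context.HYPOTHETICAL),
        ("possible métastase", Context.HYPOTHETICAL),
        # punctuation breaks the trigger scope
        ("pas de douleur, métastase confirmée", Context.AFFIRMED),
        # "mais" breaks scope too
        ("pas de fièvre mais métastase retrouvée", Context.AFFIRMED),
        # negation wins over hypothesis when both are in scope
        ("suspicion levée sans métastase", Context.NEGATED),
    ])
    def test_trigger_windows(self, lexicon, text, expected):
        doc = NormalizedDoc(text)
        (mention,) = [m for m in detect_mentions(doc, lexicon, "d1")
                      if m.category is Category.METASTASIS]
        assert classify_context(mention, doc) is expected

    def test_trigger_beyond_window_ignored(self, lexicon):
        text = "pas de signe en faveur pour le moment métastase"
        doc = NormalizedDoc(text)
        (mention,) = detect_mentions(doc, lexicon, "d1")
        assert classify_context(mention, doc) is Context.AFFIRMED


# ---------------------------------------------------------------------------
# date linking
# ---------------------------------------------------------------------------

class TestDates:
    def test_no_date_in_sentence(self, lexicon):
        sd = process_document(_doc("Métastase osseuse. Revu le 24/05/2022."), lexicon)
        met = [m for m in sd.mentions if m.category is Category.METASTASIS]
        assert met[0].linked_date is None

    def test_concept_linked_date(self, lexicon):
        sd = process_document(_doc("métastase diagnostiquée le 24 mai 2022"), lexicon)
        (met,) = [m for m in sd.mentions if m.category is Category.METASTASIS]
        assert met.linked_date == Date(2022, 5, 24)

    def test_nearest_date_wins(self, lexicon):
        text = "Le 02/03/2020 un scanner readressé est discuté : métastase le 04/05/2021."
        sd = process_document(_doc(text), lexicon)
        (met,) = [m for m in sd.mentions if m.category is Category.METASTASIS]
        # oracle: exhaustive token-gap computation over normalized text
        doc = NormalizedDoc(redact := text)
        dates = detect_dates(doc, "d1")
        norm = doc.norm
        spans = {}
        for d in dates:
            s = normalize_text(redact[d.start:d.end])[0]
            i = norm.index(s)
            spans[d.linked_date] = (i, i + len(s))
        i = norm.index("metastase")
        gaps = {v: token_gap_oracle(norm, (i, i + len("metastase")), sp)
                for v, sp in spans.items()}
        assert met.linked_date == min(gaps, key=gaps.get)
        assert met.linked_date == Date(2021, 5, 4)

    def test_invalid_date_dropped(self, lexicon):
        sd = process_document(_doc("métastase le 31/02/2022"), lexicon)
        assert not any(m.category is Category.DATE for m in sd.mentions)
        (met,) = [m for m in sd.mentions if m.category is Category.METASTASIS]
        assert met.linked_date is None

    def test_date_mentions_carry_their_value(self, lexicon):
        sd = process_document(_doc("Vu le 3 août 2021."), lexicon)
        (d,) = [m for m in sd.mentions if m.category is Category.DATE]
        assert d.linked_date == Date(2021, 8, 3)


# ---------------------------------------------------------------------------
# relations + whole pipeline
# ---------------------------------------------------------------------------

class TestPipeline:
    def test_empty_text(self, lexicon):
        sd = process_document(_doc(""), lexicon)
        assert sd.mentions == []

    def test_missing_field_rejected(self, lexicon):
        with pytest.raises(ValueError, match="doc_date"):
            process_document({"doc_id": "d", "patient_id": "p", "text": "x"}, lexicon)

    def test_response_links_to_treatment(self, lexicon):
        sd = process_document(_doc("Réponse partielle après chimiothérapie."), lexicon)
        (resp,) = [m for m in sd.mentions if m.category is Category.TREATMENT_RESPONSE]
        assert resp.related_to is not None
        target = sd.mentions[resp.related_to]
        assert target.category is Category.TREATMENT and target.code == "CHEMO"

    def test_metastasis_links_to_location(self, lexicon):
        sd = process_document(_doc("Métastase du poumon confirmée."), lexicon)
        (met,) = [m for m in sd.mentions if m.category is Category.METASTASIS]
        assert sd.mentions[met.related_to].category is Category.TUMOR_LOCATION

    def test_relation_scope_is_the_sentence(self, lexicon):
        sd = process_document(_doc("Chimiothérapie en cours. Réponse partielle."), lexicon)
        (resp,) = [m for m in sd.mentions if m.category is Category.TREATMENT_RESPONSE]
        assert resp.related_to is None

    def test_exactly_one_context_per_mention(self, lexicon, small_noisy_bundle):
        from oncotext.io import document_to_dict

        docs = small_noisy_bundle.centres[0].documents[:30]
        for d in docs:
            sd = process_document(document_to_dict(d), lexicon)
            for m in sd.mentions:
                assert m.context in (Context.AFFIRMED, Context.NEGATED,
                                     Context.HYPOTHETICAL)

    def test_span_fidelity_on_corpus(self, lexicon, small_noisy_bundle):
        """Every reported span normalizes back to a vocabulary term."""
        from oncotext.io import document_to_dict

        docs = small_noisy_bundle.centres[0].documents[:40]
        for d in docs:
            sd = process_document(document_to_dict(d), lexicon)
            for m in sd.mentions:
                if m.category is Category.DATE:
                    continue
                surface = sd.redacted_text[m.start:m.end]
                assert normalize_text(surface)[0] in lexicon
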