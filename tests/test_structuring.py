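"""Deduplication, discharge corroboration, onset heuristic, profile assembly."""

from __future__ import annotations

from datetime import date as Date
from datetime import timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncotext.config import OnsetParams
from oncotext.structuring import (
    build_profile,
    build_profile_with_diagnostics,
    corroborate_with_discharge,
    deduplicate_occurrences,
    infer_metastasis_onset,
)
from oncotext.types import (
    UNKNOWN_PRIMARY,
    Category,
    Context,
    DateOrigin,
    EventKind,
    SourceKind,
)

from .conftest import make_occurrence
from .oracles import brute_force_onset

D0 = Date(2019, 1, 1)


# ---------------------------------------------------------------------------
# strategies: randomized occurrence sets with binary-exact weights
# ---------------------------------------------------------------------------

_occurrence = st.builds(
    make_occurrence,
    date=st.integers(0, 3 * 365).map(lambda d: D0 + timedelta(days=d)),
    category=st.sampled_from([Category.METASTASIS, Category.RELAPSE,
                              Category.TUMOR_LOCATION]),
    code=st.sampled_from([None, "DISTANT", "LOCAL", "C50.9"]),
    context=st.sampled_from(list(Context)),
    origin=st.sampled_from(list(DateOrigin)),
    source=st.sampled_from(list(SourceKind)),
    source_id=st.sampled_from([f"s{i}" for i in range(8)]),
    occurrence_id=st.uuids().map(str),
)
_occurrence_sets = st.lists(_occurrence, max_size=50)

_params = st.builds(
    OnsetParams,
    interval_days=st.sampled_from([90, 180, 365]),
    source_weight=st.fixed_dictionaries({
        SourceKind.PMSI: st.sampled_from([1.0, 2.0, 3.0]),
        SourceKind.REPORT: st.sampled_from([0.5, 1.0]),
    }),
    date_origin_weight=st.fixed_dictionaries({
        DateOrigin.CONCEPT_LINKED: st.sampled_from([1.0, 1.5, 2.0]),
        DateOrigin.DOCUMENT: st.just(1.0),
    }),
    hypothetical_weight=st.sampled_from([0.0, 0.25, 0.5]),
    threshold=st.sampled_from([1.0, 2.0, 3.0, 5.0]),
)


class TestDeduplication:
    def test_distinct_unchanged(self):
        occ = [make_occurrence(D0, source_id="a"),
               make_occurrence(D0 + timedelta(days=1), source_id="b")]
        assert len(deduplicate_occurrences(occ)) == 2

    def test_history_copies_collapse(self):
        """The same mention repeated in five history sections, carrying the
        same concept-linked date, yields one occurrence."""
        occ = [
            make_occurrence(D0, origin=DateOrigin.CONCEPT_LINKED,
                            source_id=f"d{i}", occurrence_id=f"d{i}:0")
            for i in range(5)
        ]
        assert len(deduplicate_occurrences(occ)) == 1

    def test_concept_linked_representative_kept(self):
        a = make_occurrence(D0, origin=DateOrigin.DOCUMENT, source_id="a")
        b = make_occurrence(D0, origin=DateOrigin.CONCEPT_LINKED, source_id="b")
        (kept,) = deduplicate_occurrences([a, b])
        assert kept.date_origin is DateOrigin.CONCEPT_LINKED

    @settings(max_examples=100, deadline=None)
    @given(_occurrence_sets)
    def test_idempotent_and_never_grows(self, occ):
        once = deduplicate_occurrences(occ)
        assert len(once) <= len(occ)
        assert deduplicate_occurrences(once) == once


class TestCorroboration:
    def test_no_pmsi_no_flags(self):
        occ = [make_occurrence(D0, category=Category.TUMOR_LOCATION, code="C50.4")]
        assert not any(o.corroborated for o in corroborate_with_discharge(occ))

    def test_prefix_match_within_window(self):
        rep = make_occurrence(Date(2021, 2, 1), category=Category.TUMOR_LOCATION,
                              code="C50.4")
        stay = make_occurrence(Date(2021, 2, 10), category=Category.TUMOR_LOCATION,
                               code="C50.9", source=SourceKind.PMSI, source_id="s1")
        out = corroborate_with_discharge([rep, stay])
        assert [o.corroborated for o in out if o.source is SourceKind.REPORT] == [True]

    def test_outside_window_not_corroborated(self):
        rep = make_occurrence(Date(2021, 2, 1), category=Category.TUMOR_LOCATION,
                              code="C50.4")
        stay = make_occurrence(Date(2022, 2, 1), category=Category.TUMOR_LOCATION,
                               code="C50.9", source=SourceKind.PMSI, source_id="s1")
        out = corroborate_with_discharge([rep, stay])
        assert not any(o.corroborated for o in out if o.source is SourceKind.REPORT)

    def test_treatment_matched_by_act_type(self):
        rep = make_occurrence(Date(2021, 2, 1), category=Category.TREATMENT,
                              code="CHEMO")
        stay = make_occurrence(Date(2021, 2, 15), category=Category.TREATMENT,
                               code="Z51.1", source=SourceKind.PMSI, source_id="s1")
        (flagged,) = [o for o in corroborate_with_discharge([rep, stay])
                      if o.source is SourceKind.REPORT]
        assert flagged.corroborated

    @settings(max_examples=60, deadline=None)
    @given(_occurrence_sets, _occurrence)
    def test_adding_pmsi_is_monotone(self, occ, extra):
        """Adding a coded stay never removes a corroboration flag."""
        extra_pmsi = make_occurrence(
            extra.date, category=extra.category, code=extra.code,
            source=SourceKind.PMSI, source_id="s-extra",
            occurrence_id="s-extra:0")
        before = {o.occurrence_id: o.corroborated
                  for o in corroborate_with_discharge(occ)}
        after = {o.occurrence_id: o.corroborated
                 for o in corroborate_with_discharge(occ + [extra_pmsi])}
        for oid, flag in before.items():
            if flag:
                assert after[oid]


class TestOnsetHeuristic:
    def test_no_candidates(self):
        diag = infer_metastasis_onset([], OnsetParams())
        assert diag.chosen_onset is None and diag.windows == []

    def test_single_weighted_occurrence(self):
        """One coded-stay metastasis (weight 2.0) clears a 1.5 threshold."""
        occ = [make_occurrence(Date(2020, 3, 10), source=SourceKind.PMSI)]
        params = OnsetParams(threshold=1.5)
        diag = infer_metastasis_onset(occ, params)
        assert diag.chosen_onset == Date(2020, 3, 10)
        assert [w.accepted for w in diag.windows] == [True]

    def test_below_threshold_no_onset(self):
        occ = [make_occurrence(Date(2020, 3, 10))]  # report, weight 1.0
        diag = infer_metastasis_onset(occ, OnsetParams())
        assert diag.chosen_onset is None
        assert all(not w.accepted for w in diag.windows)

    def test_negated_excluded_hypothetical_downweighted(self):
        params = OnsetParams(threshold=0.2)
        neg = [make_occurrence(D0, context=Context.NEGATED)]
        assert infer_metastasis_onset(neg, params).chosen_onset is None
        hyp = [make_occurrence(D0, context=Context.HYPOTHETICAL)]
        assert infer_metastasis_onset(hyp, params).chosen_onset == D0

    def test_at_most_one_accepted_window(self):
        occ = [make_occurrence(D0 + timedelta(days=k), source=SourceKind.PMSI,
                               source_id=f"s{k}") for k in range(10)]
        diag = infer_metastasis_onset(occ, OnsetParams())
        assert sum(w.accepted for w in diag.windows) == 1

    @settings(max_examples=200, deadline=None)
    @given(_occurrence_sets, _params)
    def test_matches_brute_force_oracle(self, occ, params):
        assert (infer_metastasis_onset(occ, params).chosen_onset
                == brute_force_onset(occ, params))

    @settings(max_examples=100, deadline=None)
    @given(_occurrence_sets, st.integers(0, 3 * 365))
    def test_affirmed_occurrence_never_delays_onset(self, occ, day):
        """Adding affirmed metastatic evidence keeps the onset or moves it
        earlier, never later."""
        params = OnsetParams()
        extra = make_occurrence(D0 + timedelta(days=day), source=SourceKind.PMSI,
                                source_id="s-extra", occurrence_id="x:0")
        before = infer_metastasis_onset(occ, params).chosen_onset
        after = infer_metastasis_onset(occ + [extra], params).chosen_onset
        if before is not None:
            assert after is not None and after <= before

    @settings(max_examples=100, deadline=None)
    @given(_occurrence_sets)
    def test_raising_threshold_only_delays(self, occ):
        lo = infer_metastasis_onset(occ, OnsetParams(threshold=2.0)).chosen_onset
        hi = infer_metastasis_onset(occ, OnsetParams(threshold=4.0)).chosen_onset
        if hi is not None:
            assert lo is not None and lo <= hi


class TestProfiles:
    def test_zero_occurrences_empty_profile(self):
        profile = build_profile([], OnsetParams())
        assert profile.cancers == [] and profile.acts == []

    def test_single_location_no_metastasis(self):
        occ = [make_occurrence(D0, category=Category.TUMOR_LOCATION, code="C50.9")]
        profile = build_profile(occ, OnsetParams())
        (cancer,) = profile.cancers
        assert cancer.primary_site == "C50.9"
        kinds = [e.kind for e in cancer.tumor_events]
        assert kinds == [EventKind.PRIMARY]

    def test_unknown_primary_from_keywords(self):
        occ = [
            make_occurrence(D0, category=Category.UNKNOWN_PRIMARY_KEYWORD),
            make_occurrence(D0 + timedelta(days=3), source=SourceKind.PMSI,
                            source_id="s1"),
            make_occurrence(D0 + timedelta(days=10), source=SourceKind.PMSI,
                            source_id="s2"),
        ]
        profile = build_profile(occ, OnsetParams())
        (cancer,) = profile.cancers
        assert cancer.primary_site == UNKNOWN_PRIMARY

    def test_synthetic_cup_patient(self, small_noisy_bundle, noisy_profiles):
        """CUP ground truth resolves to an unknown primary with a metastatic
        event at diagnosis."""
        cups = [c for c in small_noisy_bundle.courses if c.is_cup]
        assert cups, "corpus contains CUP patients"
        for course in cups:
            profile, _ = noisy_profiles[course.patient_id]
            (cancer,) = profile.cancers
            assert cancer.primary_site == UNKNOWN_PRIMARY
            met = [e for e in cancer.tumor_events
                   if e.kind is EventKind.METASTATIC_RELAPSE]
            assert met and abs((met[0].date - cancer.diagnosis_date).days) <= 30

    def test_primary_resolution_on_corpus(self, small_noisy_bundle, noisy_profiles):
        ok = total = 0
        for course in small_noisy_bundle.courses:
            if course.is_cup:
                continue
            profile, _ = noisy_profiles[course.patient_id]
            total += 1
            if profile.cancers and profile.cancers[0].primary_site == course.primary_site:
                ok += 1
        assert ok / total >= 0.95

    def test_events_sorted_and_valid(self, noisy_profiles):
        for profile, _ in noisy_profiles.values():
            profile.validate()

    def test_onset_rule_skipped_without_candidates(self):
        occ = [make_occurrence(D0, category=Category.TUMOR_LOCATION, code="C50.9")]
        _, diag = build_profile_with_diagnostics(occ, OnsetParams())
        assert diag.windows == [] and diag.chosen_onset is None
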