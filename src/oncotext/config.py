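"""Configuration models (pydantic) and YAML loading.

Two tunable blocks matter scientifically:

* :class:`CorpusConfig` — the study conditions under which synthetic corpora
  are generated (cohort size, metastatic fraction, noise rates, number of
  centres).  Identical configs always regenerate byte-identical corpora.
* :class:`OnsetParams` — the weighting scheme of the metastasis-onset
  heuristic (window length, per-source and per-date-origin weights,
  hypothetical down-weighting, acceptance threshold).
"""

from __future__ import annotations

from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .types import DateOrigin, SourceKind


class CorpusConfig(BaseModel):
    """Parameters of the synthetic corpus generator."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(500, gt=0)
    #: fraction of patients whose cancer has no identifiable primary (CUP).
    #: CUP is a rare presentation, under 5% of cancers; the default sits in
    #: the middle of the plausible range.
    cup_prevalence: float = Field(0.04, ge=0.0, le=0.05)
    #: fraction of non-CUP patients who develop metastatic disease.
    metastatic_fraction: float = Field(0.4, ge=0.0, le=1.0)
    reports_per_patient: tuple[int, int] = (6, 12)
    #: probability that a follow-up report repeats the initial history
    #: section verbatim (reports habitually carry a rarely-updated history).
    history_redundancy_prob: float = Field(0.8, ge=0.0, le=1.0)
    #: per-report probability of an injected negated metastasis mention.
    negation_rate: float = Field(0.2, ge=0.0, le=1.0)
    #: per-report probability of an injected hypothetical metastasis mention.
    hypothesis_rate: float = Field(0.1, ge=0.0, le=1.0)
    #: probability that a mention carries its own date phrase (otherwise the
    #: document date is the downstream fallback).
    explicit_date_rate: float = Field(0.6, ge=0.0, le=1.0)
    n_centres: int = Field(4, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_range(self) -> "CorpusConfig":
        lo, hi = self.reports_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("reports_per_patient must be a 1 <= lo <= hi range")
        return self


class OnsetParams(BaseModel):
    """Weights and threshold of the sliding-interval onset heuristic.

    The heuristic accumulates occurrence weights inside windows of
    ``interval_days`` and accepts the first window whose total weight
    exceeds ``threshold``.  Coded discharge data is weighted above report
    text, a concept-linked date above a document-date fallback, and
    hypothetical mentions are strongly down-weighted (negated ones are
    excluded before the heuristic runs).
    """

    model_config = ConfigDict(frozen=True)

    interval_days: int = Field(180, gt=0)
    source_weight: dict[SourceKind, float] = Field(
        default_factory=lambda: {SourceKind.PMSI: 2.0, SourceKind.REPORT: 1.0}
    )
    date_origin_weight: dict[DateOrigin, float] = Field(
        default_factory=lambda: {DateOrigin.CONCEPT_LINKED: 1.5, DateOrigin.DOCUMENT: 1.0}
    )
    hypothetical_weight: float = Field(0.25, ge=0.0)
    threshold: float = Field(3.0, gt=0.0)

    def weight_of(self, source: SourceKind, origin: DateOrigin, hypothetical: bool) -> float:
        w = self.source_weight[source] * self.date_origin_weight[origin]
        return w * self.hypothetical_weight if hypothetical else w


class QuerySettings(BaseModel):
    """Operational tolerances of cohort query criteria."""

    model_config = ConfigDict(frozen=True)

    #: "metastatic at diagnosis" = a metastatic event dated within this many
    #: days of the diagnosis date.
    de_novo_window_days: int = Field(30, ge=0)


class Settings(BaseModel):
    """Top-level config file: ``corpus:``, ``onset:``, ``query:`` blocks."""

    corpus: CorpusConfig = CorpusConfig()
    onset: OnsetParams = OnsetParams()
    query: QuerySettings = QuerySettings()


def load_settings(path: str) -> Settings:
    with open(path, "r", encoding="utf-8") as fh:
        raw: Any = yaml.safe_load(fh) or {}
    return Settings.model_validate(raw)
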