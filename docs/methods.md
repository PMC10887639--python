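# Methods

## Overview

`oncotext` models the path from free-text oncology records to research
cohorts in four layers: raw documents (reports and coded discharge
stays), an *elementary* model of dated concept occurrences with
provenance, an *inferred* per-patient model (cancer → tumor events →
acts → documents), and count-only federated queries over the inferred
model plus raw text. Everything is deterministic: identical inputs and
seeds reproduce byte-identical artifacts.

## Concept extraction

The extraction pipeline is deliberately rule-based rather than
statistical: a closed lexicon, exact matching, and transparent context
rules. This makes the gold-standard behaviour of the whole stack
checkable — mention spans, assertion labels and linked dates can be
compared character-for-character against the generator's annotations.

* **Normalization.** Lowercasing, diacritic stripping (NFD, combining
  marks dropped), apostrophe unification, whitespace collapsing. An
  offset map carries every normalized character back to its original
  span, so reported spans always index the (redacted) source text,
  0-based half-open. The original text is never mutated for span
  reporting.
* **Lemmatization** is a suffix rule only (final plural `-s`/`-x` on
  alphabetic tokens longer than three characters), applied on both
  sides of the match. A full lemmatizer adds nothing for a
  lexicon-closed vocabulary. French function words are *retained*
  during phrase matching: several vocabulary phrases ("de primitif
  inconnu", "recherche de la tumeur primitive") contain them.
* **Matching** is longest-match-first, left-to-right, non-overlapping,
  over lemmatized token sequences; at equal length the leftmost match
  wins. Date phrases (both `24 mai 2022` and `24/05/2022` forms) are
  detected first and their tokens are excluded from lexicon matching;
  an unparseable date surface (e.g. `31/02/2022`) is dropped with a log
  line rather than failing the document.
* **Assertion context.** NegEx-style: a trigger in a backward window of
  5 tokens, with no intervening scope breaker (clause punctuation or
  "mais"), flips the mention to NEGATED ("pas de", "absence de",
  "sans", "aucun(e)") or HYPOTHETICAL ("suspicion", "évoque",
  "possible", "probable", "recherche de"). Negation takes precedence
  when both are in scope. Triggers inside a matched phrase do not count
  — "pas de primitif retrouve" is itself an affirmed unknown-primary
  phrase.
* **Date linking.** A concept links to the nearest date phrase in its
  sentence within 10 tokens (ties to the leftmost); otherwise its
  occurrence later falls back to the document date. Sentence boundaries
  are `.`, `!`, `?`.
* **Relation linking** is sentence-scoped: a treatment response links
  to the nearest treatment mention (preferring a preceding one, since
  either order occurs in practice: "réponse partielle après
  chimiothérapie"); a metastasis links to a co-sentence tumor location
  when present.
* **Redaction** runs first and replaces e-mails, titled person names
  and digit runs of six or more with typed placeholders; it is
  idempotent and the placeholders cannot re-match.

## Elementary model

One occurrence per non-date mention, dated by its linked date (origin
`CONCEPT_LINKED`) or the document date (origin `DOCUMENT`). Coded stays
contribute occurrences at their admission date: C77–C79 codes as
metastasis, other C-codes as tumor location, session-encounter codes
(Z51.0/Z51.1) as treatment, always AFFIRMED — billing data has no
textual context. Ingestion is additive and order-independent (set
semantics on occurrence identity), and every occurrence traces to
exactly one source id. C80 ("malignant neoplasm, unspecified site") is
stored as a location occurrence but never resolves a primary: it is the
coded face of an unidentified primary.

## Patient structuring

Rules run in a fixed order: deduplicate → corroborate → resolve primary
→ date metastasis onset (only when candidates exist) → assemble acts.

* **Deduplication** collapses occurrences identical on (category, code,
  date, context), keeping the representative with the richest
  provenance: concept-linked over document-dated, coded stay over
  report, then smallest source id. This is what neutralises verbatim
  history sections — the same sentence re-ingested from five reports
  with the same linked date collapses to one occurrence; undated
  history copies still differ by document date and are handled by the
  windowing below.
* **Corroboration**: a report diagnosis is confirmed by a coded stay
  sharing its 3-character ICD-10 category within ±90 days; a report
  treatment by a compatible coded act/encounter (chemo/immuno ↔ Z51.1,
  radio ↔ Z51.0, surgery ↔ CCAM act) in the same window. Flags are
  monotone in the discharge data. The ±90-day window is one
  chemotherapy line's typical span; it is a constant, not config, since
  nothing downstream is sensitive to it at desk scale.
* **Primary resolution**: most frequent corroborated affirmed location
  code, falling back to the most frequent affirmed location when no
  discharge data corroborates anything (ties to the lexicographically
  smallest code). Diagnosis date is the earliest affirmed occurrence of
  the winning code. When no location is affirmed but unknown-primary
  phrases occur, the primary is `UNKNOWN_PRIMARY` and the diagnosis
  date is the earliest of those phrases or affirmed metastases.

### Metastasis-onset heuristic

Candidates are non-negated metastasis occurrences plus distant-relapse
occurrences (relapse mentions whose wording places them away from the
primary; local relapses are local-relapse events, not onset evidence).
Windows start at each distinct candidate date in chronological order
and span `interval_days`. Each candidate weighs

    source_weight[source] × date_origin_weight[origin] × (hypothetical_weight if hypothetical)

and the first window whose total exceeds `threshold` is accepted; its
start date is the onset. Diagnostics expose every evaluated window.

Defaults (all config-exposed under the `onset:` YAML block):

| parameter             | default | rationale |
|-----------------------|---------|-----------|
| `interval_days`       | 180     | middle of the plausible 3/6/12-month range for clustering repeat documentation of one progression event |
| `source_weight`       | PMSI 2.0, report 1.0 | coded billing data is deliberate, audited documentation |
| `date_origin_weight`  | concept-linked 1.5, document 1.0 | an explicit date phrase is stronger evidence than a document-date fallback |
| `hypothetical_weight` | 0.25    | suspicions often precede confirmation, so they contribute, weakly; negations are excluded outright |
| `threshold`           | 3.0     | roughly "one coded stay plus one dated report mention", or three independent report mentions — more than any plausible lone false positive |

Two monotonicity properties hold by construction and are
property-tested: adding affirmed evidence never delays the onset, and
raising the threshold never advances it. The implementation is verified
against an exhaustive brute-force window enumeration on randomized
instances. Weight sums in tests use binary-exact values so float
associativity cannot blur the threshold comparison. The inferred
metastatic event date is clamped to be no earlier than the diagnosis
date (an earlier suspicion window may legitimately start before it);
the unclamped window start remains visible in diagnostics.

Coded stays participate in onset windows as weighted evidence rather
than only corroborating: withholding the strongest-dated source from
the estimator would discard exactly the signal it needs.

## Federated queries

A query combines a keyword criterion (any phrase, matched with the same
normalization/lemmatization as extraction, over raw report text) with
structured criteria on profiles (diagnosed since a date, metastatic at
diagnosis within a 30-day tolerance, required primary site), combined
as ALL or ANY. Keyword search intentionally ignores assertion context:
it is a recall-oriented textual screen, and its phrase list includes
negation-embedding phrases on purpose. The built-in
cancer-of-unknown-primary query exists as a base single-phrase form and
a refined ten-phrase form ("ACUP", "primitif inconnu", "de primitif
inconnu", "sans primitif retrouve", "sans primitif connu", "d'origine
indéterminée", "pas de primitif retrouve", "d'origine inconnue",
"recherche de la tumeur primitive", "autre primitif").

Federation is in-process over per-centre directories — the transport
layer is a deployment detail; the contract is that only per-centre
counts are aggregated, a failed centre is omitted and reported, and the
total is invariant to any disjoint re-partition of patients.

## Evaluation design

Recall is computed against a reference list of known cases; precision
on a reviewed sample of predictions when exhaustive review is
impossible (every reviewed id must have been predicted); true negatives
are reported as unavailable, so specificity is never computed. F1 is
the harmonic mean; interpretation bands are half-open on the left:
[0, 0.6) poor, [0.6, 0.8) acceptable, [0.8, 0.9) excellent, [0.9, 1]
outstanding. Reported percentages round half away from zero to integer
percent; F1 is reported to two decimals.

## What the synthetic corpus does and does not emulate

The generator *does* reproduce: verbatim-repeated history sections
(default probability 0.8 per follow-up report), negated and
hypothetical metastasis mentions (defaults 0.2 and 0.1 per report),
explicit date phrases on a fraction of mentions (default 0.6, in both
long and numeric French formats, with accented and unaccented keyword
spellings), CUP prevalence of 4% (below the <5% epidemiological bound),
a 40% metastatic fraction with one in five presenting de novo,
unknown-primary wording in the early work-up of some de-novo metastatic
non-CUP patients (the period-of-diagnostic-uncertainty false
positives), chemotherapy delivered as coded 21-day session stays
without drug detail, and secondary-malignancy codes on post-onset
stays.

It does *not* emulate: vocabulary outside the closed lexicon, spelling
errors, ambiguous or discontinuous date expressions, multiple primaries
per patient, haematological/sarcoma presentations where histology
outranks location, inter-centre coding-practice variation, or genuinely
adversarial negation scopes. Passing tests therefore demonstrate the
correctness of the *mechanisms* (matching, windowing, weighting,
federation, metrics) under realistic-shaped noise — not the expected
extraction accuracy on real clinical text, where a learned recognizer
would be needed.

Default study conditions: 500 patients, 6–12 reports each, four
centres partitioned round-robin by patient index (reproducible and
balanced). These sizes exercise every code path at full statistical
strength for the properties tested while keeping any run in seconds.

## Degenerate inputs and tie-breaks

Empty documents yield empty mention lists; an unknown patient queries
to an empty occurrence list, not an error; zero occurrences build an
empty profile; an empty candidate set yields no onset and no windows.
Duplicate ids in evaluation inputs are set semantics. Equal-date
occurrences order by source id then occurrence id everywhere a stable
order matters.

## Known limitations

* The lexicon is small and curated; recall on real text is bounded by
  it. The architecture accepts any CSV lexicon, but no statistical
  fallback exists.
* Primary resolution is location-frequency based; it mis-handles
  cancers where morphology should dominate.
* One cancer per patient is inferred; metachronous second primaries
  collapse onto the most frequent location.
* The de-novo-metastatic tolerance (30 days) and corroboration window
  (90 days) are pragmatic constants validated only on synthetic data.
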