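# Methods

## Problem and model

Spontaneous reporting systems (SRS) collect post-marketing reports of
suspected adverse drug events. Each report carries a set of drugs and a set
of MedDRA-style adverse-event (AE) terms; standard pharmacovigilance screens
one drug against one event at a time. `ademiner` instead mines *multi-item*
associations — rules

    A → B,   A a set of drugs, B a set of events,

with A and B disjoint by type. For an itemset X, the support S(X) is the
number of reports containing every item of X, over N reports in total. Each
rule carries

* confidence C(A→B) = S(A∪B) / S(A), an estimate of Pr(B | A);
* relative reporting ratio RR = S(A∪B)·N / (S(A)·S(B)), the observed joint
  frequency over the frequency expected if drug sets and event sets were
  reported independently. RR = 1 is independence; RR > 1 a positive
  association.

Confidence is reported but never used for screening: a frequent event (e.g.
nausea) gets high confidence under any antecedent, and a rare but strongly
associated event gets low confidence. Screening keeps rules with
S(A∪B) ≥ `min_support` and RR ≥ `min_rr`; the *multi-item* filter
additionally requires |A| + |B| ≥ 3 (at least 2 drugs or 2 events), which is
where drug–drug-interaction-type signals live. Found rules are hypotheses
for expert review, not established adverse events: reporting biases,
duplicate reports and confounding all survive into RR.

## Mining algorithm

The miner is level-wise Apriori over typed items, with two tailorings:

1. **Typed rule emission.** Frequent itemsets of every composition
   (drug-only, event-only, mixed) are generated — the drug-only and
   event-only sets are needed both for downward-closure pruning and as the
   S(A), S(B) denominators — but exactly one rule is emitted per *mixed*
   frequent itemset: antecedent = its drug part, consequent = its event
   part. This replaces the 2^k−2 antecedent/consequent partitions of
   unconstrained rule generation and matches the definition of a
   drug→event association. Because the frequent list is downward closed,
   S(A) and S(B) are lookups, never recounts; a missing subset raises
   `MiningConsistencyError` (it would indicate a miner bug).

2. **Posting-list support counting.** An inverted index maps each item to
   the set of report ids containing it. Each frequent itemset carries its
   supporting-report set; a size-k candidate built by joining two (k−1)-sets
   sharing a (k−2)-prefix is counted with a single set intersection.
   The public `itemset_support` intersects postings smallest-first and can
   short-circuit once the running intersection falls below a support floor.

Item order is total and fixed — DRUG before EVENT, lexicographic id within
kind — so candidate generation, output order and file output are
deterministic. `brute_force_mine` is the oracle: full enumeration of all
itemsets up to `max_size` with full-scan counting, refused above 20 distinct
items; the test suite asserts exact agreement (itemsets, supports, rules,
RR values) on 50+ random corpora.

`max_size` defaults to 8, comfortably above the largest associations such
screens report in practice; raise it only with a support threshold high
enough to keep level widths bounded.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_support` | 50 | minimum reports containing the full rule; a screening point sized for ~10^5-report corpora — lower it proportionally on smaller corpora |
| `min_rr` | 2.0 | minimum relative reporting ratio; 2 is the conventional disproportionality screen |
| `max_size` | 8 | largest itemset considered |
| `multi_item_only` | on | keep only rules with ≥ 3 items |
| `serious_codes` | {DE, LT, HO, DS, CA, RI} | outcome codes counted as "serious"; empty set disables the filter |
| `min_drugs_per_report` | 2 | report-level selection (drug-interaction focus); 0 disables |

At `min_support` = 50 no variance shrinkage (e.g. empirical-Bayes/GPS
adjustment) is applied: at that support the adjusted and unadjusted RR are
nearly equal, and shrinkage estimators are deliberately out of scope.

RR is held at full float precision internally (computed as one
correctly-rounded division of exact integer products, so the identity
RR = C·N/S(B) holds to well under one ulp against exact rational
arithmetic); rule files render 4 significant digits.

## Drug-name normalization

SRS drug fields are free text. Cleanup is deterministic and idempotent, in a
fixed order: uppercase → strip `/.../` annotations → strip parenthesized
qualifiers (innermost first, so nesting unwinds) → strip trailing dose/form
tokens (numbers, units, "TABLETS", "SOLUTION", …; the pattern list is
configurable and makes no claim of completeness) → collapse whitespace.
A string that cleans to nothing raises `UnmappableDrugName` and the caller
keeps the raw name. Brand→generic mapping is a two-column TSV lookup on the
cleaned string; misses return the cleaned string unchanged, so mapping is
total. No NLP extraction, terminology-service lookup, or fuzzy matching is
performed; correctness of the mapping is the table author's responsibility.
The pipeline normalizes *before* the minimum-drugs filter so that
brand/generic collapse is reflected in the per-report drug count.

## Synthetic corpora and what they show

`synthetic.generate_corpus` emits a corpus of `n_reports` reports in which

* per-report item counts are min + Poisson: drugs = 2 + Poisson(1.3)
  (mean 3.3, minimum 2 mirroring the >1-drug selection), events =
  1 + Poisson(2.4) (mean 3.4) — chosen to match the corpus-level statistics
  of large post-selection SRS samples;
* items are drawn without replacement from Zipf(1.0) rank marginals over
  500 drugs and 300 events (exact weighted sampling via Gumbel top-k), so
  item frequencies are heavy-tailed as in real SRS data;
* background drug sets and event sets are drawn independently, so every
  non-planted association is a false positive by construction;
* each planted rule contributes `n_case_reports` case reports (carved out of
  `n_reports`) containing its drug set plus background padding and, with
  probability `penetrance`, its full event set — so planted rules are not
  trivially separable from background;
* optional whole-report duplication appends floor(rate·N) copies with fresh
  ids, reproducing the duplicate-reporting artifact that inflates RR.

`expected_rule_stats` gives closed-form approximate expectations (item
inclusion ≈ 1 − (1−p)^mean-count, joint inclusion as the product) used to
size planted rules; the five default planted rules have expected joint
support ≥ 100 and expected RR ≥ 5 at 20,000 reports.

What passing these studies does **not** show about real data: the generator
has no confounding structure (no indication-driven co-prescription), no
correlated event terms, no under/over-reporting dynamics, and drug names are
already canonical — so recovery and calibration results bound the method's
behaviour under its own model assumptions only.

## Validation studies (recomputed by `scripts/acceptance.py`)

* the naive candidate-space bound for 2-drug/3-event rules over 10,000-item
  vocabularies (10,000^5 = 10^20), the motivation for constrained search;
* exact Apriori/brute-force agreement on 50 random corpora (≤ 10 drugs,
  ≤ 8 events, ≤ 300 reports, random thresholds);
* the four-report worked example (7 frequent itemsets at support 2, 3 rules,
  one multi-item survivor at RR ≥ 1);
* planted-signal recovery: 20,000 reports, 5 planted multi-item rules,
  screening at (50, 2) — recall and the fraction of planted rules in the
  top decile of the RR ranking over all candidate rules (ranking over the
  screened survivors alone would be ill-posed when few rules survive);
* null calibration: the same generator with nothing planted — mean RR over
  drug–event pairs with support ≥ 50;
* the RR = C·N/S(B) identity in ulps over every rule mined above;
* normalization: nine brand-name spelling variants collapsing to one generic
  through a two-line map, and cleanup idempotence over 10,000 random strings.

Desk-scale corpora (2·10^4 reports) run the full pipeline in seconds; the
algorithm's posting-intersection counting is what keeps database-scale runs
(10^5–10^6 reports) tractable.

## Numerical and degenerate-input choices

* Ties in ranking break by descending joint support, then lexicographic
  antecedent and consequent — a declared, deterministic total order (no
  claim that any particular published ordering used the same tie-break).
* Duplicate report ids keep the first occurrence with a warning; malformed
  transaction records are skipped and counted, not fatal.
* Reports with no events are retained and contribute to drug-side supports
  only; reports with no drugs survive ingestion but are removed by the
  default `min_drugs_per_report` = 2 filter.
* Undecodable bytes in AERS-style ASCII input are replaced and logged;
  a wrong per-row column count is a hard error naming file and line.
* Empty corpora: `corpus_stats` raises; the pipeline writes a header-only
  rule file and exits 0.
* Drug role codes (PS/SS/C/I) are read and summarized but never filter
  items: suspect and concomitant drugs all enter mining.
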