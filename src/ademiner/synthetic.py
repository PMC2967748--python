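"""Synthetic spontaneous-report corpora with known ground truth.

Emulates the shape of a post-selection reporting-system corpus: every report
carries at least two drugs and at least one event, item frequencies are
heavy-tailed (Zipf-ranked marginals), drug sets and event sets are drawn
independently in background reports, and a configurable set of *planted*
drug-set→event-set associations is injected via dedicated case reports.
Whole-report duplication (the near-identical follow-up/duplicate-report
artifact of real reporting systems) can be layered on top.

Because background drugs and events are independent, any association the
miner finds outside the planted truth is a false positive by construction —
which is what makes the generator usable for recall/calibration studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reports import Report

__all__ = [
    "PlantedRule",
    "SyntheticSpec",
    "RealizedRuleStats",
    "GroundTruth",
    "ExpectedRuleStats",
    "drug_name",
    "event_name",
    "default_planted_rules",
    "generate_corpus",
    "inject_duplicates",
    "expected_rule_stats",
]


def drug_name(rank: int) -> str:
    """Vocabulary drug identifier for 1-based Zipf rank."""
    return f"DRUG_{rank:04d}"


def event_name(rank: int) -> str:
    """Vocabulary event identifier for 1-based Zipf rank."""
    return f"EVENT_{rank:04d}"


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth association: case reports carrying ``drug_ranks`` and,
    with probability ``penetrance``, the full ``event_ranks`` set."""

    drug_ranks: tuple[int, ...]
    event_ranks: tuple[int, ...]
    n_case_reports: int
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not self.drug_ranks or not self.event_ranks:
            raise ValueError("planted rule needs non-empty drug and event sets")
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must be in (0, 1]")
        if self.n_case_reports < 0:
            raise ValueError("n_case_reports must be >= 0")

    @property
    def drug_ids(self) -> frozenset[str]:
        return frozenset(drug_name(r) for r in self.drug_ranks)

    @property
    def event_ids(self) -> frozenset[str]:
        return frozenset(event_name(r) for r in self.event_ranks)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters.

    Defaults target the corpus shape of large post-selection SRS samples:
    a mean of 3.3 distinct drugs (minimum 2, the >1-drug selection) and 3.4
    distinct events (minimum 1) per report, drawn as min + Poisson, with
    rank-1/r Zipf marginals over 500 drugs and 300 events.
    """

    n_reports: int = 20_000
    n_drugs: int = 500
    n_events: int = 300
    drug_zipf_s: float = 1.0
    event_zipf_s: float = 1.0
    min_drugs_per_report: int = 2
    mean_drugs_per_report: float = 3.3
    min_events_per_report: int = 1
    mean_events_per_report: float = 3.4
    planted: tuple[PlantedRule, ...] = ()
    duplication_rate: float = 0.0
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.n_reports < 1 or self.n_drugs < 1 or self.n_events < 1:
            raise ValueError("n_reports, n_drugs, n_events must be >= 1")
        if self.drug_zipf_s < 0 or self.event_zipf_s < 0:
            raise ValueError("Zipf exponents must be >= 0")
        if self.mean_drugs_per_report < self.min_drugs_per_report:
            raise ValueError("mean drugs per report below its minimum")
        if self.mean_events_per_report < self.min_events_per_report:
            raise ValueError("mean events per report below its minimum")
        if not 0 <= self.duplication_rate < 1:
            raise ValueError("duplication_rate must be in [0, 1)")
        n_cases = sum(p.n_case_reports for p in self.planted)
        if n_cases > self.n_reports:
            raise ValueError("planted case reports exceed n_reports")
        for p in self.planted:
            if max(p.drug_ranks) > self.n_drugs or min(p.drug_ranks) < 1:
                raise ValueError(f"planted drug rank out of vocabulary: {p.drug_ranks}")
            if max(p.event_ranks) > self.n_events or min(p.event_ranks) < 1:
                raise ValueError(f"planted event rank out of vocabulary: {p.event_ranks}")
        return self


@dataclass(frozen=True)
class RealizedRuleStats:
    """Exact, full-scan statistics of one planted rule in an emitted corpus."""

    drug_ids: frozenset[str]
    event_ids: frozenset[str]
    support_joint: int
    support_ante: int
    support_cons: int
    n_reports: int

    @property
    def rr(self) -> float:
        if not self.support_ante or not self.support_cons:
            return math.nan
        return (self.support_joint * self.n_reports) / (
            self.support_ante * self.support_cons
        )


@dataclass
class GroundTruth:
    """Planted rules with their realized corpus statistics."""

    rules: list[RealizedRuleStats] = field(default_factory=list)

    def is_planted(self, drug_ids: frozenset[str], event_ids: frozenset[str]) -> bool:
        return any(
            r.drug_ids == drug_ids and r.event_ids == event_ids for r in self.rules
        )


def _zipf_probs(n: int, s: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks**-s
    return w / w.sum()


def _sample_counts(
    rng: np.random.Generator, n: int, minimum: int, mean: float, cap: int
) -> np.ndarray:
    counts = minimum + rng.poisson(mean - minimum, size=n)
    return np.minimum(counts, cap)


def _sample_item_sets(
    rng: np.random.Generator, counts: np.ndarray, probs: np.ndarray
) -> list[np.ndarray]:
    """Weighted sampling without replacement per row via Gumbel top-k: the
    items with the k largest log(p)+Gumbel keys are an exact sample."""
    n = len(counts)
    keys = np.log(probs)[None, :] + rng.gumbel(size=(n, len(probs)))
    order = np.argsort(-keys, axis=1)
    return [order[i, : counts[i]] for i in range(n)]


def realized_stats(
    corpus: Sequence[Report], planted: Sequence[PlantedRule]
) -> GroundTruth:
    """Recompute each planted rule's joint/marginal supports by full scan."""
    drug_sets = [frozenset(i.id for i in r.drugs) for r in corpus]
    event_sets = [frozenset(i.id for i in r.events) for r in corpus]
    n = len(corpus)
    truth = GroundTruth()
    for p in planted:
        a, b = p.drug_ids, p.event_ids
        s_ante = sum(a <= d for d in drug_sets)
        s_cons = sum(b <= e for e in event_sets)
        s_joint = sum(a <= d and b <= e for d, e in zip(drug_sets, event_sets))
        truth.rules.append(
            RealizedRuleStats(a, b, s_joint, s_ante, s_cons, n_reports=n)
        )
    return truth


def generate_corpus(spec: SyntheticSpec) -> tuple[list[Report], GroundTruth]:
    """Emit a corpus under ``spec`` plus the realized ground truth.

    Total corpus size is ``spec.n_reports``: planted case reports are carved
    out of it and the remainder is independent background.  Case reports also
    receive background items (padding to the per-report count distributions),
    so planted rules are not trivially separable.  Every report gets a
    "serious" outcome code, emulating a post-selection sample.  All
    randomness flows from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    drug_probs = _zipf_probs(spec.n_drugs, spec.drug_zipf_s)
    event_probs = _zipf_probs(spec.n_events, spec.event_zipf_s)
    n_cases = sum(p.n_case_reports for p in spec.planted)
    n_bg = spec.n_reports - n_cases

    corpus: list[Report] = []

    def emit(idx: int, drug_idx, extra_event_idx, forced_events: frozenset[str] = frozenset()):
        drugs = {drug_name(int(i) + 1) for i in drug_idx}
        events = set(forced_events) | {event_name(int(i) + 1) for i in extra_event_idx}
        corpus.append(
            Report.build(f"S{idx:06d}", drugs=drugs, events=events, outcomes=["HO"])
        )

    # independent background
    bg_drug_counts = _sample_counts(
        rng, n_bg, spec.min_drugs_per_report, spec.mean_drugs_per_report, spec.n_drugs
    )
    bg_event_counts = _sample_counts(
        rng, n_bg, spec.min_events_per_report, spec.mean_events_per_report, spec.n_events
    )
    bg_drugs = _sample_item_sets(rng, bg_drug_counts, drug_probs)
    bg_events = _sample_item_sets(rng, bg_event_counts, event_probs)
    for i in range(n_bg):
        emit(i, bg_drugs[i], bg_events[i])

    # planted case reports, padded with background items
    idx = n_bg
    for p in spec.planted:
        m = p.n_case_reports
        drug_counts = _sample_counts(
            rng, m, spec.min_drugs_per_report, spec.mean_drugs_per_report, spec.n_drugs
        )
        extra_drug_counts = np.maximum(drug_counts - len(p.drug_ranks), 0)
        event_counts = _sample_counts(
            rng, m, spec.min_events_per_report, spec.mean_events_per_report, spec.n_events
        )
        case_drugs = _sample_item_sets(rng, extra_drug_counts, drug_probs)
        case_events = _sample_item_sets(rng, event_counts, event_probs)
        penetrant = rng.random(m) < p.penetrance
        planted_drug_idx = np.array([r - 1 for r in p.drug_ranks])
        for j in range(m):
            forced = p.event_ids if penetrant[j] else frozenset()
            emit(
                idx,
                np.concatenate([planted_drug_idx, case_drugs[j]]),
                case_events[j],
                forced,
            )
            idx += 1

    if spec.duplication_rate:
        corpus = inject_duplicates(
            corpus, spec.duplication_rate, seed=int(rng.integers(2**31))
        )

    return corpus, realized_stats(corpus, spec.planted)


def inject_duplicates(
    corpus: Sequence[Report], rate: float, seed: int
) -> list[Report]:
    """Append whole-report copies (fresh ids, identical items) of randomly
    chosen reports until the added count equals floor(rate × N)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    corpus = list(corpus)
    n_add = int(rate * len(corpus))
    if not n_add:
        return corpus
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(corpus), size=n_add)
    for j, i in enumerate(picks):
        src = corpus[int(i)]
        corpus.append(
            Report(
                report_id=f"{src.report_id}~DUP{j}",
                drugs=src.drugs,
                events=src.events,
                outcome_codes=src.outcome_codes,
                drug_roles=src.drug_roles,
                period=src.period,
            )
        )
    return corpus


@dataclass(frozen=True)
class ExpectedRuleStats:
    """Closed-form (approximate) expectations used to size a spec so planted
    rules clear the screening thresholds."""

    expected_joint: float
    expected_ante: float
    expected_cons: float
    expected_rr: float


def expected_rule_stats(spec: SyntheticSpec) -> list[ExpectedRuleStats]:
    """Per planted rule: expected joint support (cases × penetrance plus a
    background-coincidence term) and the implied approximate RR.

    Item inclusion in a background report is approximated as
    1 − (1 − p_i)^m with m the mean items per report; joint inclusion of a
    set as the product (ignores the small without-replacement correction and
    cross-rule case contributions).
    """
    spec.validate()
    drug_probs = _zipf_probs(spec.n_drugs, spec.drug_zipf_s)
    event_probs = _zipf_probs(spec.n_events, spec.event_zipf_s)
    n = spec.n_reports
    n_bg = n - sum(p.n_case_reports for p in spec.planted)

    def incl(p: float, mean_k: float) -> float:
        return 1.0 - (1.0 - p) ** mean_k

    out: list[ExpectedRuleStats] = []
    for p in spec.planted:
        pa = math.prod(
            incl(drug_probs[r - 1], spec.mean_drugs_per_report) for r in p.drug_ranks
        )
        pb = math.prod(
            incl(event_probs[r - 1], spec.mean_events_per_report)
            for r in p.event_ranks
        )
        cases = p.n_case_reports
        e_joint = cases * p.penetrance + n_bg * pa * pb
        e_ante = cases + n_bg * pa
        e_cons = cases * p.penetrance + n_bg * pb
        e_rr = e_joint * n / (e_ante * e_cons)
        out.append(ExpectedRuleStats(e_joint, e_ante, e_cons, e_rr))
    return out


def default_planted_rules() -> tuple[PlantedRule, ...]:
    """The five multi-item planted rules used throughout validation: mid-rank
    vocabulary items, case counts and penetrances sized so each rule's
    expected joint support is ≥ 100 and expected RR ≥ 5 in the default
    20,000-report corpus."""
    return (
        PlantedRule(drug_ranks=(50, 60), event_ranks=(40,), n_case_reports=150, penetrance=0.9),
        PlantedRule(drug_ranks=(55, 65, 75), event_ranks=(45,), n_case_reports=150, penetrance=0.9),
        PlantedRule(drug_ranks=(70, 80), event_ranks=(50, 60), n_case_reports=150, penetrance=0.9),
        PlantedRule(drug_ranks=(90, 100, 110), event_ranks=(70, 80), n_case_reports=140, penetrance=0.95),
        PlantedRule(drug_ranks=(120, 130), event_ranks=(90,), n_case_reports=160, penetrance=0.85),
    )
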