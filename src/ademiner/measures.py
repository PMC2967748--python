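"""Rule-strength measures, threshold screening and ranking.

For a rule A→B over N reports, with S(·) the number of reports containing an
itemset:

* confidence  C(A→B) = S(A∪B) / S(A), an estimate of Pr(B|A);
* relative reporting ratio  RR = S(A∪B)·N / (S(A)·S(B)), the observed joint
  frequency over the frequency expected if the drugs and the events were
  reported independently.  RR = 1 means independence; RR > 1 a positive
  association.

Confidence is computed and reported but never used for screening: a common
event yields high confidence for any drug, and a rare one low confidence no
matter how strong the association.  Screening is by joint support and RR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .errors import ConfigError, MeasureUndefinedError
from .reports import DEFAULT_SERIOUS_CODES, Item, ItemKind

__all__ = [
    "confidence",
    "relative_reporting_ratio",
    "AssociationRule",
    "MiningConfig",
    "ScreenResult",
    "screen_rules",
    "rank_rules",
    "naive_candidate_space",
]


def confidence(support_joint: int, support_ante: int) -> float:
    """S(A∪B)/S(A); undefined when S(A) = 0."""
    if support_ante <= 0:
        raise MeasureUndefinedError("confidence undefined for S(A) = 0")
    if not 0 <= support_joint <= support_ante:
        raise ValueError("need 0 <= S(A∪B) <= S(A)")
    return support_joint / support_ante


def relative_reporting_ratio(
    support_joint: int, support_ante: int, support_cons: int, n: int
) -> float:
    """S(A∪B)·N / (S(A)·S(B)); undefined when either marginal support is 0.

    Computed as a single division of exact integer products, so the result is
    the correctly rounded float of the exact ratio.
    """
    if support_ante <= 0 or support_cons <= 0:
        raise MeasureUndefinedError("RR undefined for S(A) = 0 or S(B) = 0")
    if n < max(support_ante, support_cons):
        raise ValueError("N must be at least each marginal support")
    return (support_joint * n) / (support_ante * support_cons)


@dataclass(frozen=True)
class AssociationRule:
    """A drugs→events rule with its counts and measures."""

    antecedent: frozenset[Item]
    consequent: frozenset[Item]
    support_joint: int
    support_ante: int
    support_cons: int
    n_reports: int
    confidence: float
    rr: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if any(i.kind is not ItemKind.DRUG for i in self.antecedent):
            raise ValueError("antecedent must contain only DRUG items")
        if any(i.kind is not ItemKind.EVENT for i in self.consequent):
            raise ValueError("consequent must contain only EVENT items")
        if not (
            self.support_joint
            <= min(self.support_ante, self.support_cons)
            <= self.n_reports
        ):
            raise ValueError("need S(A∪B) <= min(S(A), S(B)) <= N")

    @classmethod
    def from_counts(
        cls,
        antecedent: frozenset[Item],
        consequent: frozenset[Item],
        support_joint: int,
        support_ante: int,
        support_cons: int,
        n_reports: int,
    ) -> "AssociationRule":
        return cls(
            antecedent=antecedent,
            consequent=consequent,
            support_joint=support_joint,
            support_ante=support_ante,
            support_cons=support_cons,
            n_reports=n_reports,
            confidence=confidence(support_joint, support_ante),
            rr=relative_reporting_ratio(
                support_joint, support_ante, support_cons, n_reports
            ),
        )

    @property
    def n_items(self) -> int:
        return len(self.antecedent) + len(self.consequent)

    def sort_key(self) -> tuple:
        """Deterministic total order: RR desc, joint support desc, then
        lexicographic antecedent and consequent."""
        return (
            -self.rr,
            -self.support_joint,
            tuple(sorted(i.id for i in self.antecedent)),
            tuple(sorted(i.id for i in self.consequent)),
        )


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and switches for one mining run.

    ``min_support`` and ``min_rr`` default to 50 and 2, a screening point
    chosen for large (~10^5-report) corpora; ``multi_item_only`` keeps rules
    whose combined itemset has at least 3 items (at least 2 drugs or 2
    events).  ``min_drugs_per_report`` = 0 disables the report-level drug
    filter; an empty ``serious_codes`` disables the seriousness filter.
    """

    min_support: int = 50
    min_rr: float = 2.0
    max_size: int = 8
    multi_item_only: bool = True
    serious_codes: frozenset[str] = DEFAULT_SERIOUS_CODES
    min_drugs_per_report: int = 2
    seed: int = 0

    def validate(self) -> "MiningConfig":
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")
        if not self.min_rr > 0:
            raise ConfigError("min_rr must be > 0")
        if self.max_size < 2:
            raise ConfigError("max_size must be >= 2")
        if self.min_drugs_per_report < 0:
            raise ConfigError("min_drugs_per_report must be >= 0")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "MiningConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "serious_codes" in data:
            data = {**data, "serious_codes": frozenset(data["serious_codes"])}
        return cls(**data).validate()


@dataclass
class ScreenResult(Sequence):
    """Surviving rules plus the screening counts.

    ``n_pass_thresholds`` counts rules passing support and RR regardless of
    size; ``n_multi_item`` counts those that are additionally multi-item —
    the two figures a run reports side by side.  Behaves as a sequence of the
    surviving rules.
    """

    rules: list[AssociationRule]
    n_input: int
    n_pass_thresholds: int
    n_multi_item: int

    def __len__(self) -> int:
        return len(self.rules)

    def __getitem__(self, i):
        return self.rules[i]

    def __iter__(self) -> Iterator[AssociationRule]:
        return iter(self.rules)


def screen_rules(rules: Iterable[AssociationRule], config: MiningConfig) -> ScreenResult:
    """Keep rules with S(A∪B) ≥ min_support and RR ≥ min_rr, and — when
    ``multi_item_only`` — at least 3 items in total."""
    rules = list(rules)
    pass_thresholds = [
        r
        for r in rules
        if r.support_joint >= config.min_support and r.rr >= config.min_rr
    ]
    multi = [r for r in pass_thresholds if r.n_items >= 3]
    survivors = multi if config.multi_item_only else pass_thresholds
    return ScreenResult(
        rules=survivors,
        n_input=len(rules),
        n_pass_thresholds=len(pass_thresholds),
        n_multi_item=len(multi),
    )


def rank_rules(rules: Iterable[AssociationRule]) -> list[AssociationRule]:
    """Sort descending by RR, ties broken by descending joint support, then
    lexicographic antecedent and consequent — a deterministic total order."""
    return sorted(rules, key=AssociationRule.sort_key)


def naive_candidate_space(
    n_drug_vocab: int, n_event_vocab: int, n_drugs: int, n_events: int
) -> int:
    """Naive size of the candidate space for rules with ``n_drugs`` drugs and
    ``n_events`` events over the given vocabularies: vocab^count on each side
    (the back-of-envelope bound that motivates pruned search — e.g. 2 drugs
    and 3 events over 10,000-item vocabularies is 10,000^5 = 10^20)."""
    if min(n_drug_vocab, n_event_vocab, n_drugs, n_events) < 1:
        raise ValueError("all arguments must be >= 1")
    return n_drug_vocab**n_drugs * n_event_vocab**n_events
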