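"""Typed, constrained Apriori frequent-itemset mining over report corpora.

The miner is level-wise Apriori with two tailorings for adverse-event
screening:

1. *Typed rule constraint* — rules are emitted only for mixed itemsets
   (at least one drug and one event), as antecedent = the drug part and
   consequent = the event part.  Drug-only and event-only frequent itemsets
   are still generated and retained: downward-closure pruning needs them, and
   they supply the S(A) and S(B) denominators of the reporting-ratio measure.

2. *Posting-list support counting* — an inverted index maps each item to the
   set of report ids containing it; candidate support is the size of a
   posting intersection (smallest posting first, with an early exit once the
   running intersection cannot reach the support floor) instead of a full
   corpus scan.

``brute_force_mine`` is a deliberately naive full-enumeration oracle used to
cross-check the miner on small universes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .errors import MiningConsistencyError
from .measures import AssociationRule
from .reports import Item, ItemKind, Report

__all__ = [
    "ItemSet",
    "FrequentItemSet",
    "InvertedIndex",
    "build_inverted_index",
    "itemset_support",
    "apriori_frequent_itemsets",
    "emit_candidate_rules",
    "brute_force_mine",
]

BRUTE_FORCE_MAX_ITEMS = 20


@dataclass(frozen=True)
class ItemSet:
    """An ordered, duplicate-free set of typed items (drugs sort first)."""

    items: tuple[Item, ...]

    @classmethod
    def of(cls, items: Iterable[Item]) -> "ItemSet":
        ordered = tuple(sorted(set(items)))
        if not ordered:
            raise ValueError("ItemSet must be non-empty")
        return cls(ordered)

    @property
    def drug_part(self) -> tuple[Item, ...]:
        return tuple(i for i in self.items if i.kind is ItemKind.DRUG)

    @property
    def event_part(self) -> tuple[Item, ...]:
        return tuple(i for i in self.items if i.kind is ItemKind.EVENT)

    @property
    def is_mixed(self) -> bool:
        return bool(self.drug_part) and bool(self.event_part)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)


@dataclass(frozen=True)
class FrequentItemSet:
    """An itemset together with its support (number of reports containing it)."""

    itemset: ItemSet
    support: int


@dataclass(frozen=True)
class InvertedIndex:
    """Item → set-of-report-ids postings over a corpus of N reports."""

    postings: dict[Item, frozenset[str]]
    n_reports: int


def build_inverted_index(corpus: Sequence[Report]) -> InvertedIndex:
    """Build complete, exact postings; singleton support is posting size."""
    if not corpus:
        raise ValueError("cannot index an empty corpus")
    acc: dict[Item, set[str]] = {}
    for rep in corpus:
        for item in rep.items:
            acc.setdefault(item, set()).add(rep.report_id)
    return InvertedIndex(
        postings={item: frozenset(ids) for item, ids in acc.items()},
        n_reports=len(corpus),
    )


def itemset_support(itemset: ItemSet, index: InvertedIndex) -> int:
    """Exact support of an itemset: size of the intersection of its postings,
    intersected smallest-first.  An item with no posting gives support 0."""
    return len(_supporting_reports(itemset.items, index))


def _supporting_reports(
    items: Sequence[Item], index: InvertedIndex, floor: int = 0
) -> frozenset[str]:
    """Intersection of postings, smallest posting first.  With ``floor`` > 0,
    returns early (possibly a partial intersection) once the running result
    drops below the floor — the caller only learns 'infrequent'."""
    if not items:
        raise ValueError("itemset must be non-empty")
    postings = []
    for item in items:
        p = index.postings.get(item)
        if p is None:
            return frozenset()
        postings.append(p)
    postings.sort(key=len)
    acc = postings[0]
    for p in postings[1:]:
        acc = acc & p
        if floor and len(acc) < floor:
            return acc
    return acc


def apriori_frequent_itemsets(
    corpus: Sequence[Report], min_support: int, max_size: int = 8
) -> list[FrequentItemSet]:
    """All itemsets of size ≤ ``max_size`` with support ≥ ``min_support``.

    Level-wise generation: size-k candidates join two frequent (k−1)-sets
    sharing a (k−2)-prefix in item order, pruned unless every (k−1)-subset is
    frequent.  Each frequent itemset's supporting-report set is carried
    forward, so counting a candidate is one set intersection.  Output is
    deterministic: sorted by size, then item order.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if not corpus:
        return []
    index = build_inverted_index(corpus)

    # level 1
    tidsets: dict[tuple[Item, ...], frozenset[str]] = {
        (item,): posting
        for item, posting in index.postings.items()
        if len(posting) >= min_support
    }
    result: list[FrequentItemSet] = [
        FrequentItemSet(ItemSet((key[0],)), len(tids)) for key, tids in tidsets.items()
    ]

    level_keys = sorted(tidsets)
    k = 1
    while level_keys and k < max_size:
        k += 1
        next_tidsets: dict[tuple[Item, ...], frozenset[str]] = {}
        frequent_prev = set(level_keys)
        for i, a in enumerate(level_keys):
            prefix = a[:-1]
            for b in level_keys[i + 1 :]:
                if b[:-1] != prefix:
                    break  # sorted order: no further shared prefix
                candidate = a + (b[-1],)
                if k > 2 and any(
                    candidate[:j] + candidate[j + 1 :] not in frequent_prev
                    for j in range(k - 2)  # dropping a[-1] or b[-1] gives a or b
                ):
                    continue
                tids = tidsets[a] & tidsets[b]
                if len(tids) >= min_support:
                    next_tidsets[candidate] = tids
        result.extend(
            FrequentItemSet(ItemSet(key), len(tids)) for key, tids in next_tidsets.items()
        )
        tidsets = next_tidsets
        level_keys = sorted(next_tidsets)

    result.sort(key=lambda f: (len(f.itemset.items), f.itemset.items))
    return result


def emit_candidate_rules(
    frequent: Sequence[FrequentItemSet], index: InvertedIndex
) -> list[AssociationRule]:
    """One rule per mixed frequent itemset: drug part → event part.

    S(A) and S(B) are looked up from the frequent list itself — downward
    closure guarantees both parts are present; a miss indicates a mining bug
    and raises MiningConsistencyError.  No drug-only or event-only output.
    """
    support_of: dict[tuple[Item, ...], int] = {
        f.itemset.items: f.support for f in frequent
    }
    rules: list[AssociationRule] = []
    for f in frequent:
        if not f.itemset.is_mixed:
            continue
        ante, cons = f.itemset.drug_part, f.itemset.event_part
        try:
            s_ante = support_of[ante]
            s_cons = support_of[cons]
        except KeyError as exc:
            raise MiningConsistencyError(
                f"frequent list is not downward-closed: missing subset {exc.args[0]}"
            ) from exc
        rules.append(
            AssociationRule.from_counts(
                antecedent=frozenset(ante),
                consequent=frozenset(cons),
                support_joint=f.support,
                support_ante=s_ante,
                support_cons=s_cons,
                n_reports=index.n_reports,
            )
        )
    return rules


def brute_force_mine(
    corpus: Sequence[Report], min_support: int, max_size: int = 8
) -> list[FrequentItemSet]:
    """Oracle miner: enumerate every itemset up to ``max_size`` and count
    support by full corpus scan.  Same output contract (content and order) as
    ``apriori_frequent_itemsets``; refuses universes over
    ``BRUTE_FORCE_MAX_ITEMS`` items."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not corpus:
        return []
    universe = sorted(set().union(*(r.items for r in corpus)))
    if len(universe) > BRUTE_FORCE_MAX_ITEMS:
        raise ValueError(
            f"brute-force enumeration refused: {len(universe)} items > {BRUTE_FORCE_MAX_ITEMS}"
        )
    report_sets = [r.items for r in corpus]
    result: list[FrequentItemSet] = []
    for k in range(1, min(max_size, len(universe)) + 1):
        for combo in combinations(universe, k):
            cset = frozenset(combo)
            support = sum(cset <= rep for rep in report_sets)
            if support >= min_support:
                result.append(FrequentItemSet(ItemSet(combo), support))
    result.sort(key=lambda f: (len(f.itemset.items), f.itemset.items))
    return result
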