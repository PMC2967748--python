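"""Deterministic drug-string cleanup and brand→generic mapping.

Drug names in spontaneous reports arrive as free text with heavy variation:
brand names, salts, parenthesized qualifiers, slash-delimited annotations and
dose/form suffixes ("AVANDIA /SCH/ (ROSIGLITAZONE MALEATE)", "AVANDIA
(2 MILLIGRAM TABLETS)", ...).  Left unmapped, this variation dilutes a signal
across many synonymous item identifiers.

Cleanup here is rule-based and idempotent; mapping to a canonical generic
identifier is table-driven (a user-supplied two-column TSV).  A name missing
from the table is left as its cleaned form — mapping is total and never
errors on a miss.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import UnmappableDrugName
from .reports import Item, Report

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DOSE_FORM_PATTERNS",
    "clean_drug_string",
    "DrugMap",
    "map_to_generic",
    "NormalizationSummary",
    "normalize_reports",
]

# Trailing tokens stripped as dose/form noise.  The list is configurable and
# makes no claim of completeness; it covers the common AERS-style suffixes.
DEFAULT_DOSE_FORM_PATTERNS: tuple[str, ...] = (
    r"\d+(?:\.\d+)?",                      # bare numbers: "2", "0.5"
    r"\d+(?:\.\d+)?(?:MG|MCG|UG|G|ML|IU)", # fused number+unit: "2MG"
    r"MG|MILLIGRAMS?|MICROGRAMS?|MCG|UG|GRAMS?|MILLILITERS?|ML|IU",
    r"TABLETS?|TABS?|CAPSULES?|CAPS?|PILLS?",
    r"INJECTIONS?|SOLUTION|SUSPENSION|SYRUP|CREAM|OINTMENT|GEL|PATCH(?:ES)?|DROPS?|SPRAY",
    r"ORAL|TOPICAL|INTRAVENOUS|IV|IM|SUBCUTANEOUS",
)

_SLASH_ANNOTATION = re.compile(r"/[^/]*/")
_PARENTHESIZED = re.compile(r"\([^()]*\)")


def _compile_trailing(patterns: Sequence[str]) -> re.Pattern:
    alt = "|".join(f"(?:{p})" for p in patterns)
    return re.compile(rf"(?:^|\s)(?:{alt})$")


_DEFAULT_TRAILING = _compile_trailing(DEFAULT_DOSE_FORM_PATTERNS)


def clean_drug_string(raw: str, dose_form_patterns: Sequence[str] | None = None) -> str:
    """Clean a raw drug string to its canonical lookup form.

    Fixed order: uppercase → strip ``/.../`` annotations → strip ``(...)``
    qualifiers (innermost-first, so nesting unwinds) → strip trailing
    dose/form tokens to a fixpoint → collapse whitespace.  The result is
    idempotent: cleaning a cleaned string is a no-op.

    Raises
    ------
    UnmappableDrugName
        If nothing is left after cleanup; the caller should keep the raw
        string instead.
    """
    trailing = (
        _DEFAULT_TRAILING if dose_form_patterns is None else _compile_trailing(dose_form_patterns)
    )
    s = raw.upper()
    s = _SLASH_ANNOTATION.sub(" ", s)
    while True:
        s, n = _PARENTHESIZED.subn(" ", s)
        if not n:
            break
    s = " ".join(s.split())
    while True:
        m = trailing.search(s)
        if not m:
            break
        s = s[: m.start()].rstrip()
    s = " ".join(s.split())
    if not s:
        raise UnmappableDrugName(raw)
    return s


@dataclass(frozen=True)
class DrugMap:
    """Lookup table from cleaned drug strings to canonical generic identifiers.

    Keys must already be in cleaned form (cleanup is a no-op on them); values
    are non-empty.  A generic may map to itself.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            if not value:
                raise ValueError(f"drug map value for {key!r} is empty")
            if clean_drug_string(key) != key:
                raise ValueError(f"drug map key {key!r} is not in cleaned form")

    @classmethod
    def load(cls, path: str | Path) -> "DrugMap":
        """Load a two-column TSV (cleaned name, generic identifier)."""
        entries: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            entries[parts[0].strip()] = parts[1].strip()
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)


def map_to_generic(cleaned: str, drug_map: DrugMap) -> str:
    """Return the canonical generic for a cleaned name, or the name unchanged
    when it is absent from the table (mapping is total)."""
    return drug_map.entries.get(cleaned, cleaned)


@dataclass
class NormalizationSummary:
    """Name-reduction bookkeeping from one normalization pass."""

    n_raw_names: int
    n_normalized_names: int
    n_mapped: int
    n_unmapped: int
    n_uncleanable: int


def normalize_reports(
    corpus: Iterable[Report], drug_map: DrugMap | None = None
) -> tuple[list[Report], NormalizationSummary]:
    """Replace every drug item by ``map_to_generic(clean_drug_string(raw))``.

    Distinct raw names collapsing to one generic become a single item per
    report (set semantics).  Event items are already case/whitespace
    normalized by the Report constructor and are left untouched.  Returns the
    normalized corpus and a summary of the name-space reduction.
    """
    drug_map = drug_map or DrugMap()
    raw_names: set[str] = set()
    out_names: set[str] = set()
    n_mapped = n_unmapped = n_uncleanable = 0
    cache: dict[str, str] = {}

    def canonical(raw: str) -> str:
        nonlocal n_mapped, n_unmapped, n_uncleanable
        if raw in cache:
            return cache[raw]
        try:
            cleaned = clean_drug_string(raw)
        except UnmappableDrugName:
            n_uncleanable += 1
            cache[raw] = raw
            return raw
        generic = map_to_generic(cleaned, drug_map)
        if generic != cleaned:
            n_mapped += 1
        else:
            n_unmapped += 1
        cache[raw] = generic
        return generic

    normalized: list[Report] = []
    for rep in corpus:
        new_drugs = set()
        new_roles: dict[str, str] = {}
        for item in rep.drugs:
            raw_names.add(item.id)
            name = canonical(item.id)
            out_names.add(name)
            new_drugs.add(Item.drug(name))
            if rep.drug_roles and item.id in rep.drug_roles:
                new_roles.setdefault(name, rep.drug_roles[item.id])
        normalized.append(
            Report(
                report_id=rep.report_id,
                drugs=frozenset(new_drugs),
                events=rep.events,
                outcome_codes=rep.outcome_codes,
                drug_roles=new_roles or None,
                period=rep.period,
            )
        )
    summary = NormalizationSummary(
        n_raw_names=len(raw_names),
        n_normalized_names=len(out_names),
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        n_uncleanable=n_uncleanable,
    )
    logger.info(
        "drug-name normalization: %d raw names -> %d canonical (%d mapped, %d left as cleaned)",
        summary.n_raw_names,
        summary.n_normalized_names,
        summary.n_mapped,
        summary.n_unmapped,
    )
    return normalized, summary
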