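"""Spontaneous-report data model and file I/O.

A *report* is one spontaneous adverse-event record: a set of drug items, a
set of adverse-event items, and patient outcome codes.  Items live in reports
as sets — support counting is per *report*, so within-report multiplicity is
deliberately discarded.

Two input dialects are supported:

* a simple line-delimited transactions format (JSON lines, or a flat TSV with
  pipe-joined item lists), and
* an AERS-style quarterly ASCII dialect: ``$``-delimited DEMO/DRUG/REAC/OUTC
  files joined on the report key in the first column.
"""

from __future__ import annotations

import csv
import json
import logging
import statistics
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ItemKind",
    "Item",
    "Report",
    "CorpusStats",
    "DEFAULT_SERIOUS_CODES",
    "read_transactions",
    "write_transactions",
    "read_aers_ascii_quarter",
    "filter_serious",
    "filter_min_drugs",
    "corpus_stats",
    "write_rules",
]

#: AERS-style outcome codes counted as "serious": death, life-threatening,
#: hospitalization, disability, congenital anomaly, required intervention.
#: "OT" (other) is deliberately not serious.
DEFAULT_SERIOUS_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI"})


class ItemKind(IntEnum):
    """Item type; DRUG sorts before EVENT."""

    DRUG = 0
    EVENT = 1


def _norm_token(text: str) -> str:
    """Uppercase and collapse internal whitespace."""
    return " ".join(str(text).upper().split())


@dataclass(frozen=True, order=True)
class Item:
    """A typed token: a drug identifier or an adverse-event term.

    Equality and ordering are by ``(kind, id)``; DRUG items order before
    EVENT items, lexicographic within a kind.
    """

    kind: ItemKind
    id: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("Item id must be non-empty")

    @classmethod
    def drug(cls, raw: str) -> "Item":
        return cls(ItemKind.DRUG, _norm_token(raw))

    @classmethod
    def event(cls, raw: str) -> "Item":
        return cls(ItemKind.EVENT, _norm_token(raw))


@dataclass(frozen=True)
class Report:
    """One spontaneous report."""

    report_id: str
    drugs: frozenset[Item]
    events: frozenset[Item]
    outcome_codes: frozenset[str] = frozenset()
    drug_roles: Mapping[str, str] | None = None
    period: str | None = None

    @classmethod
    def build(
        cls,
        report_id: str,
        drugs: Iterable[str] = (),
        events: Iterable[str] = (),
        outcomes: Iterable[str] = (),
        roles: Mapping[str, str] | None = None,
        period: str | None = None,
    ) -> "Report":
        """Construct from raw strings, normalizing case/whitespace and
        collapsing duplicates to set membership."""
        drug_items = frozenset(Item.drug(d) for d in drugs if _norm_token(d))
        event_items = frozenset(Item.event(e) for e in events if _norm_token(e))
        outcome_set = frozenset(_norm_token(o) for o in outcomes if _norm_token(o))
        role_map = (
            {_norm_token(k): _norm_token(v) for k, v in roles.items()} if roles else None
        )
        return cls(str(report_id), drug_items, event_items, outcome_set, role_map, period)

    @property
    def items(self) -> frozenset[Item]:
        return self.drugs | self.events

    def n_items(self) -> int:
        return len(self.drugs) + len(self.events)


@dataclass
class CorpusStats:
    """Summary statistics over a corpus of reports."""

    n_reports: int
    n_unique_drugs: int
    n_unique_events: int
    mean_drugs_per_report: float
    mean_events_per_report: float
    median_drugs: float
    median_events: float
    frac_multi_drug: float
    frac_multi_event: float
    frac_three_plus_items: float
    role_fractions: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# transactions format


def _report_from_obj(obj: Mapping) -> Report:
    return Report.build(
        report_id=obj["id"],
        drugs=obj.get("drugs", ()),
        events=obj.get("events", ()),
        outcomes=obj.get("outcomes", ()),
        roles=obj.get("roles"),
        period=obj.get("period"),
    )


def _report_from_tsv_row(row: Sequence[str]) -> Report:
    def split(cell: str) -> list[str]:
        return [t for t in cell.split("|") if t.strip()]

    if len(row) < 3:
        raise ValueError("transactions TSV row needs at least 3 columns")
    outcomes = split(row[3]) if len(row) > 3 else []
    return Report.build(row[0], split(row[1]), split(row[2]), outcomes)


def read_transactions(path: str | Path, fmt: str = "auto") -> list[Report]:
    """Read a line-delimited transactions file into a list of reports.

    ``fmt`` is ``"jsonl"``, ``"tsv"``, or ``"auto"`` (sniff: a first
    non-blank line starting with ``{`` means JSON lines).  Malformed records
    are skipped with a logged warning; duplicate report ids keep the first
    occurrence.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if fmt == "auto":
        fmt = "jsonl" if lines and lines[0].lstrip().startswith("{") else "tsv"
    if fmt == "tsv" and lines and lines[0].split("\t")[0] == "report_id":
        lines = lines[1:]  # optional header row

    corpus: list[Report] = []
    seen: set[str] = set()
    n_skipped = 0
    for lineno, line in enumerate(lines, start=1):
        try:
            if fmt == "jsonl":
                rep = _report_from_obj(json.loads(line))
            elif fmt == "tsv":
                rep = _report_from_tsv_row(line.split("\t"))
            else:
                raise ValueError(f"unknown transactions format {fmt!r}")
        except (ValueError, KeyError, TypeError) as exc:
            n_skipped += 1
            logger.warning("%s:%d: skipping malformed record (%s)", path, lineno, exc)
            continue
        if rep.report_id in seen:
            logger.warning(
                "%s:%d: duplicate report id %r, keeping first", path, lineno, rep.report_id
            )
            continue
        seen.add(rep.report_id)
        corpus.append(rep)
    if n_skipped:
        logger.warning("%s: skipped %d malformed records", path, n_skipped)
    return corpus


def write_transactions(corpus: Iterable[Report], path: str | Path, fmt: str = "jsonl") -> None:
    """Write a corpus in the transactions format (inverse of read_transactions)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if fmt == "jsonl":
            for rep in corpus:
                obj = {
                    "id": rep.report_id,
                    "drugs": sorted(i.id for i in rep.drugs),
                    "events": sorted(i.id for i in rep.events),
                    "outcomes": sorted(rep.outcome_codes),
                }
                if rep.drug_roles:
                    obj["roles"] = dict(sorted(rep.drug_roles.items()))
                if rep.period:
                    obj["period"] = rep.period
                fh.write(json.dumps(obj, sort_keys=True) + "\n")
        elif fmt == "tsv":
            fh.write("report_id\tdrugs\tevents\toutcomes\n")
            for rep in corpus:
                fh.write(
                    "\t".join(
                        [
                            rep.report_id,
                            "|".join(sorted(i.id for i in rep.drugs)),
                            "|".join(sorted(i.id for i in rep.events)),
                            "|".join(sorted(rep.outcome_codes)),
                        ]
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown transactions format {fmt!r}")


# ---------------------------------------------------------------------------
# AERS-style quarterly ASCII dialect


def _read_dollar_file(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a '$'-delimited file with one header row.

    Undecodable bytes are replaced (and logged); a row whose column count
    differs from the header is a hard error naming the file and line.
    """
    path = Path(path)
    raw = path.read_bytes()
    text = raw.decode("utf-8", errors="replace")
    if "�" in text:
        logger.warning("%s: undecodable bytes replaced during read", path)
    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: missing header row")
    header = [h.strip().upper() for h in lines[0].split("$")]
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("$")
        if len(cells) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} '$'-delimited columns, got {len(cells)}"
            )
        rows.append([c.strip() for c in cells])
    return header, rows


def _col(header: list[str], names: Sequence[str], default: int | None) -> int:
    for name in names:
        if name in header:
            return header.index(name)
    if default is not None and default < len(header):
        return default
    raise ValueError(f"none of the columns {names} found in header {header}")


def read_aers_ascii_quarter(
    demo: str | Path, drug: str | Path, reac: str | Path, outc: str | Path
) -> list[Report]:
    """Join AERS-style DEMO/DRUG/REAC/OUTC files on the report key.

    One report per DEMO key, with drugs/events/outcomes aggregated by key.
    Rows in DRUG/REAC/OUTC referencing keys absent from DEMO are dropped with
    a warning.  Reports with no REAC rows get an empty event set.
    """
    demo_header, demo_rows = _read_dollar_file(demo)
    keys: list[str] = []
    seen: set[str] = set()
    for row in demo_rows:
        key = row[0]
        if key in seen:
            logger.warning("%s: duplicate report key %r, keeping first", demo, key)
            continue
        seen.add(key)
        keys.append(key)

    drugs: dict[str, list[str]] = {k: [] for k in keys}
    roles: dict[str, dict[str, str]] = {k: {} for k in keys}
    events: dict[str, list[str]] = {k: [] for k in keys}
    outcomes: dict[str, list[str]] = {k: [] for k in keys}

    header, rows = _read_dollar_file(drug)
    name_col = _col(header, ("DRUGNAME", "DRUG"), 1)
    role_col = header.index("ROLE_COD") if "ROLE_COD" in header else None
    for row in rows:
        key = row[0]
        if key not in seen:
            logger.warning("%s: drug row for unknown report key %r dropped", drug, key)
            continue
        name = row[name_col]
        if name:
            drugs[key].append(name)
            if role_col is not None and row[role_col]:
                roles[key][_norm_token(name)] = _norm_token(row[role_col])

    header, rows = _read_dollar_file(reac)
    pt_col = _col(header, ("PT", "REAC", "EVENT"), 1)
    for row in rows:
        key = row[0]
        if key not in seen:
            logger.warning("%s: reaction row for unknown report key %r dropped", reac, key)
            continue
        if row[pt_col]:
            events[key].append(row[pt_col])

    header, rows = _read_dollar_file(outc)
    oc_col = _col(header, ("OUTC_COD", "OUTC"), 1)
    for row in rows:
        key = row[0]
        if key not in seen:
            logger.warning("%s: outcome row for unknown report key %r dropped", outc, key)
            continue
        if row[oc_col]:
            outcomes[key].append(row[oc_col])

    return [
        Report.build(k, drugs[k], events[k], outcomes[k], roles[k] or None) for k in keys
    ]


# ---------------------------------------------------------------------------
# selection filters and summary statistics


def filter_serious(corpus: Iterable[Report], serious_codes: Iterable[str] = DEFAULT_SERIOUS_CODES) -> list[Report]:
    """Keep exactly the reports whose outcome codes intersect ``serious_codes``."""
    codes = frozenset(_norm_token(c) for c in serious_codes)
    if not codes:
        raise ValueError("serious_codes must be non-empty")
    return [r for r in corpus if r.outcome_codes & codes]


def filter_min_drugs(corpus: Iterable[Report], k: int = 2) -> list[Report]:
    """Keep reports with at least ``k`` distinct drugs (apply after normalization
    so brand/generic collapse is reflected)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [r for r in corpus if len(r.drugs) >= k]


def corpus_stats(corpus: Sequence[Report]) -> CorpusStats:
    """Exact counts, means, medians and proportions over a non-empty corpus."""
    if not corpus:
        raise ValueError("cannot summarize an empty corpus")
    n = len(corpus)
    drug_counts = [len(r.drugs) for r in corpus]
    event_counts = [len(r.events) for r in corpus]
    all_drugs = set().union(*(r.drugs for r in corpus))
    all_events = set().union(*(r.events for r in corpus))

    role_counts: dict[str, int] = {}
    total_roles = 0
    for r in corpus:
        for role in (r.drug_roles or {}).values():
            role_counts[role] = role_counts.get(role, 0) + 1
            total_roles += 1
    role_fractions = (
        {role: c / total_roles for role, c in sorted(role_counts.items())}
        if total_roles
        else {}
    )

    return CorpusStats(
        n_reports=n,
        n_unique_drugs=len(all_drugs),
        n_unique_events=len(all_events),
        mean_drugs_per_report=sum(drug_counts) / n,
        mean_events_per_report=sum(event_counts) / n,
        median_drugs=float(statistics.median(drug_counts)),
        median_events=float(statistics.median(event_counts)),
        frac_multi_drug=sum(c > 1 for c in drug_counts) / n,
        frac_multi_event=sum(c > 1 for c in event_counts) / n,
        frac_three_plus_items=sum(r.n_items() >= 3 for r in corpus) / n,
        role_fractions=role_fractions,
    )


# ---------------------------------------------------------------------------
# rule output

RULE_COLUMNS = (
    "antecedent",
    "consequent",
    "support",
    "support_antecedent",
    "support_consequent",
    "n_reports",
    "confidence",
    "rr",
)


def write_rules(rules: Iterable, path: str | Path) -> None:
    """Write ranked rules as TSV: one row per rule, measures rendered to four
    significant digits, deterministic byte output for fixed input."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(RULE_COLUMNS)
        for rule in rules:
            writer.writerow(
                [
                    ",".join(sorted(i.id for i in rule.antecedent)),
                    ",".join(sorted(i.id for i in rule.consequent)),
                    rule.support_joint,
                    rule.support_ante,
                    rule.support_cons,
                    rule.n_reports,
                    f"{rule.confidence:.4g}",
                    f"{rule.rr:.4g}",
                ]
            )
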