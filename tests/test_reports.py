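"""Report data model, transactions/AERS readers, filters and summary stats."""

import json
import random

import pytest

from ademiner.normalize import DrugMap, normalize_reports
from ademiner.reports import (
    DEFAULT_SERIOUS_CODES,
    Item,
    ItemKind,
    Report,
    corpus_stats,
    filter_min_drugs,
    filter_serious,
    read_aers_ascii_quarter,
    read_transactions,
    write_rules,
    write_transactions,
)


class TestItem:
    def test_normalization_and_equality(self):
        assert Item.drug("  aspirin  ") == Item.drug("ASPIRIN")
        assert Item.drug("A") != Item.event("A")

    def test_drugs_order_before_events(self):
        assert Item.drug("ZZZ") < Item.event("AAA")
        assert sorted([Item.event("A"), Item.drug("B")])[0].kind is ItemKind.DRUG

    def test_empty_id_rejected(self):
        with pytest.raises(ValueError):
            Item(ItemKind.DRUG, "")


class TestReadTransactions:
    def test_within_report_duplicates_collapse_and_casefold(self, tmp_path):
        p = tmp_path / "t.jsonl"
        p.write_text('{"id": "R1", "drugs": ["aspirin", "ASPIRIN"], "events": ["NAUSEA"]}\n')
        corpus = read_transactions(p)
        assert len(corpus) == 1
        assert corpus[0].drugs == frozenset({Item.drug("ASPIRIN")})
        assert corpus[0].events == frozenset({Item.event("NAUSEA")})

    def test_empty_file_gives_empty_corpus(self, tmp_path):
        p = tmp_path / "t.jsonl"
        p.write_text("")
        assert read_transactions(p) == []

    def test_duplicate_report_id_keeps_first_and_warns(self, tmp_path, caplog):
        p = tmp_path / "t.jsonl"
        p.write_text(
            '{"id": "R1", "drugs": ["A"], "events": ["X"]}\n'
            '{"id": "R1", "drugs": ["B"], "events": ["Y"]}\n'
        )
        with caplog.at_level("WARNING"):
            corpus = read_transactions(p)
        assert len(corpus) == 1
        assert corpus[0].drugs == frozenset({Item.drug("A")})
        assert any("duplicate report id" in r.message for r in caplog.records)

    def test_malformed_record_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "t.jsonl"
        p.write_text('{"id": "R1", "drugs": ["A"], "events": []}\nnot json at all {{{\n')
        with caplog.at_level("WARNING"):
            corpus = read_transactions(p)
        assert [r.report_id for r in corpus] == ["R1"]
        assert any("malformed" in r.message for r in caplog.records)

    @pytest.mark.parametrize("fmt", ["jsonl", "tsv"])
    def test_write_read_round_trip(self, tmp_path, fmt):
        corpus = [
            Report.build("R1", ["warfarin", "aspirin"], ["bleeding"], ["HO", "DE"]),
            Report.build("R2", ["metformin"], ["nausea", "headache"], ["OT"]),
        ]
        p = tmp_path / f"t.{fmt}"
        write_transactions(corpus, p, fmt=fmt)
        back = read_transactions(p, fmt=fmt)
        assert [r.report_id for r in back] == [r.report_id for r in corpus]
        assert [r.drugs for r in back] == [r.drugs for r in corpus]
        assert [r.events for r in back] == [r.events for r in corpus]
        assert [r.outcome_codes for r in back] == [r.outcome_codes for r in corpus]


def write_aers(tmp_path, demo_rows, drug_rows, reac_rows, outc_rows):
    files = {}
    for name, header, rows in [
        ("demo", "ISR$CASE$FDA_DT", demo_rows),
        ("drug", "ISR$DRUGNAME$ROLE_COD", drug_rows),
        ("reac", "ISR$PT", reac_rows),
        ("outc", "ISR$OUTC_COD", outc_rows),
    ]:
        p = tmp_path / f"{name}.txt"
        p.write_text("\n".join([header] + rows) + "\n")
        files[name] = p
    return files


class TestAersReader:
    def test_join_on_report_key(self, tmp_path):
        f = write_aers(
            tmp_path,
            demo_rows=["100$C100$20080101"],
            drug_rows=["100$AVANDIA$PS", "100$METFORMIN$C"],
            reac_rows=["100$NAUSEA"],
            outc_rows=["100$HO"],
        )
        corpus = read_aers_ascii_quarter(f["demo"], f["drug"], f["reac"], f["outc"])
        assert len(corpus) == 1
        rep = corpus[0]
        assert rep.report_id == "100"
        assert rep.drugs == frozenset({Item.drug("AVANDIA"), Item.drug("METFORMIN")})
        assert rep.events == frozenset({Item.event("NAUSEA")})
        assert rep.outcome_codes == frozenset({"HO"})
        assert rep.drug_roles == {"AVANDIA": "PS", "METFORMIN": "C"}

    def test_orphan_row_dropped_with_warning(self, tmp_path, caplog):
        f = write_aers(
            tmp_path,
            demo_rows=["100$C100$20080101"],
            drug_rows=["100$ASPIRIN$PS"],
            reac_rows=["999$NAUSEA"],
            outc_rows=[],
        )
        with caplog.at_level("WARNING"):
            corpus = read_aers_ascii_quarter(f["demo"], f["drug"], f["reac"], f["outc"])
        assert corpus[0].events == frozenset()
        assert any("unknown report key" in r.message for r in caplog.records)

    def test_report_without_reactions_has_empty_event_set(self, tmp_path):
        f = write_aers(
            tmp_path,
            demo_rows=["100$C100$20080101", "101$C101$20080102"],
            drug_rows=["100$ASPIRIN$PS", "101$IBUPROFEN$PS"],
            reac_rows=["100$NAUSEA"],
            outc_rows=[],
        )
        corpus = read_aers_ascii_quarter(f["demo"], f["drug"], f["reac"], f["outc"])
        by_id = {r.report_id: r for r in corpus}
        assert by_id["101"].events == frozenset()

    def test_wrong_column_count_is_hard_error_naming_file_and_line(self, tmp_path):
        f = write_aers(
            tmp_path,
            demo_rows=["100$C100$20080101"],
            drug_rows=["100$ASPIRIN"],  # one column short
            reac_rows=[],
            outc_rows=[],
        )
        with pytest.raises(ValueError, match=r"drug\.txt:2"):
            read_aers_ascii_quarter(f["demo"], f["drug"], f["reac"], f["outc"])

    def test_missing_header_is_hard_error(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(ValueError, match="header"):
            read_aers_ascii_quarter(p, p, p, p)


class TestFilters:
    def test_serious_kept_dropped_empty(self):
        kept = Report.build("R1", ["A", "B"], ["X"], ["HO"])
        other = Report.build("R2", ["A", "B"], ["X"], ["OT"])
        none = Report.build("R3", ["A", "B"], ["X"], [])
        out = filter_serious([kept, other, none], DEFAULT_SERIOUS_CODES)
        assert [r.report_id for r in out] == ["R1"]

    def test_serious_requires_nonempty_codes(self):
        with pytest.raises(ValueError):
            filter_serious([], set())

    def test_min_drugs_threshold(self):
        two = Report.build("R1", ["D1", "D2"], ["X"])
        one = Report.build("R2", ["D1"], ["X"])
        assert [r.report_id for r in filter_min_drugs([two, one], k=2)] == ["R1"]
        with pytest.raises(ValueError):
            filter_min_drugs([two], k=0)

    def test_min_drugs_after_brand_generic_collapse(self):
        # two raw names normalizing to one generic -> report drops below k=2
        rep = Report.build("R1", ["AVANDIA", "ROSIGLITAZONE"], ["X"])
        dmap = DrugMap({"AVANDIA": "ROSIGLITAZONE"})
        normalized, _ = normalize_reports([rep], dmap)
        assert len(normalized[0].drugs) == 1
        assert filter_min_drugs(normalized, k=2) == []

    def test_serious_and_min_drugs_commute(self, make_random_corpus):
        rng = random.Random(7)
        corpus = [
            Report.build(
                f"R{i}",
                [f"D{j}" for j in range(rng.randint(1, 4))],
                ["X"],
                [rng.choice(["HO", "OT", "DE"])],
            )
            for i in range(200)
        ]
        a = filter_min_drugs(filter_serious(corpus), k=2)
        b = filter_serious(filter_min_drugs(corpus, k=2))
        assert [r.report_id for r in a] == [r.report_id for r in b]


class TestCorpusStats:
    def test_two_report_fixture(self):
        corpus = [
            Report.build("R1", ["D1", "D2"], ["E1"]),
            Report.build("R2", ["D1"], ["E1", "E2", "E3"]),
        ]
        s = corpus_stats(corpus)
        assert s.mean_drugs_per_report == 1.5
        assert s.mean_events_per_report == 2.0
        assert s.frac_multi_drug == 0.5
        assert s.frac_three_plus_items == 1.0

    def test_single_small_report(self):
        s = corpus_stats([Report.build("R1", ["D1"], ["E1"])])
        assert s.frac_three_plus_items == 0.0
        assert s.n_unique_drugs == 1 and s.n_unique_events == 1

    def test_identical_reports_have_median_equal_mean(self):
        corpus = [Report.build(f"R{i}", ["D1", "D2"], ["E1"]) for i in range(5)]
        s = corpus_stats(corpus)
        assert s.median_drugs == s.mean_drugs_per_report == 2.0
        assert s.median_events == s.mean_events_per_report == 1.0

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            corpus_stats([])

    def test_proportions_agree_with_brute_force(self, make_random_corpus):
        corpus = make_random_corpus(11)
        s = corpus_stats(corpus)
        n = len(corpus)
        assert s.frac_multi_drug == sum(1 for r in corpus if len(r.drugs) > 1) / n
        assert s.frac_multi_event == sum(1 for r in corpus if len(r.events) > 1) / n
        assert (
            s.frac_three_plus_items
            == sum(1 for r in corpus if len(r.drugs) + len(r.events) >= 3) / n
        )

    def test_role_fractions(self):
        corpus = [
            Report.build("R1", ["A", "B"], ["X"], roles={"A": "PS", "B": "C"}),
            Report.build("R2", ["C", "D"], ["X"], roles={"C": "C", "D": "C"}),
        ]
        s = corpus_stats(corpus)
        assert s.role_fractions == {"C": 0.75, "PS": 0.25}


class TestWriteRules:
    def test_empty_rule_list_writes_header_only(self, tmp_path):
        p = tmp_path / "rules.tsv"
        write_rules([], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("antecedent\tconsequent\tsupport")

    def test_deterministic_bytes(self, tmp_path, tc4):
        from ademiner.measures import MiningConfig, rank_rules, screen_rules
        from ademiner.mine import (
            apriori_frequent_itemsets,
            build_inverted_index,
            emit_candidate_rules,
        )

        rules = rank_rules(
            emit_candidate_rules(
                apriori_frequent_itemsets(tc4, 2), build_inverted_index(tc4)
            )
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_rules(rules, p1)
        write_rules(rules, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert len(p1.read_text().splitlines()) == 1 + len(rules)
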