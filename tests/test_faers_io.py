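"""Parsing, deduplication, drug-name standardization and linking."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.faers_io import (
    FaersFormatError,
    deduplicate_cases,
    link_reports,
    parse_faers_date,
    read_ascii_table,
    standardize_drug_name,
)

from conftest import parsed, write_table

DEMO_HEADER = ["primaryid", "caseid", "fda_dt", "sex", "age", "age_cod",
               "occp_cod", "reporter_country", "event_dt"]


class TestReadAsciiTable:
    def test_row_count_preserved(self, tmp_path):
        path = write_table(
            tmp_path / "DEMO23Q1.txt",
            ["primaryid", "caseid", "fda_dt"],
            [["11", "1", "20230101"], ["21", "2", "20230202"], ["31", "3", "20230303"]],
        )
        table = read_ascii_table(path, "DEMO")
        assert len(table) == 3
        assert table.rejects == []

    def test_empty_token_is_missing(self, tmp_path):
        path = write_table(
            tmp_path / "DEMO23Q1.txt",
            ["primaryid", "caseid", "fda_dt", "sex"],
            [["100", "2015Q3", "", "F"]],
        )
        table = read_ascii_table(path, "DEMO")
        row = next(table.rows())
        assert pd.isna(row.payload["fda_dt"])
        assert row.payload["sex"] == "F"

    def test_short_line_goes_to_rejects(self, tmp_path):
        path = tmp_path / "REAC23Q1.txt"
        path.write_text(
            "primaryid$caseid$pt\n"
            "11$1$Hypotension\n"
            "21$2\n"  # one field short
            "31$3$Cough\n"
        )
        table = read_ascii_table(path, "REAC")
        assert len(table) == 2
        assert len(table.rejects) == 1
        assert table.rejects[0].line_no == 3
        assert "expected 3 fields" in table.rejects[0].reason

    def test_malformed_header_raises_naming_line(self, tmp_path):
        path = tmp_path / "DEMO23Q1.txt"
        path.write_text("justonefield\n11$1\n")
        with pytest.raises(FaersFormatError, match="line 1"):
            read_ascii_table(path, "DEMO")

    def test_latin1_fallback(self, tmp_path):
        path = tmp_path / "DEMO23Q1.txt"
        path.write_bytes(b"primaryid$caseid$fda_dt\n11$1$20230101\xe9\n")
        table = read_ascii_table(path, "DEMO")
        assert len(table) == 1


class TestDeduplicateCases:
    def test_most_recent_receipt_date_kept(self):
        demo = parsed("DEMO", ["primaryid", "caseid", "fda_dt"],
                      [["11", "1", "20230101"], ["12", "1", "20230301"]])
        out = deduplicate_cases(demo)
        assert list(out["primaryid"]) == ["12"]

    def test_unique_cases_unchanged(self):
        demo = parsed("DEMO", ["primaryid", "caseid", "fda_dt"],
                      [["11", "1", "20230101"], ["21", "2", "20230301"]])
        out = deduplicate_cases(demo)
        assert len(out) == 2
        assert sorted(out["caseid"]) == ["1", "2"]

    def test_date_tie_broken_by_numerically_larger_primaryid(self):
        demo = parsed("DEMO", ["primaryid", "caseid", "fda_dt"],
                      [["7", "1", "20230101"], ["10", "1", "20230101"]])
        out = deduplicate_cases(demo)
        assert list(out["primaryid"]) == ["10"]

    def test_unparseable_date_loses(self):
        demo = parsed("DEMO", ["primaryid", "caseid", "fda_dt"],
                      [["99", "1", "not-a-date"], ["11", "1", "20200101"]])
        with pytest.warns(UserWarning, match="unparseable"):
            out = deduplicate_cases(demo)
        assert list(out["primaryid"]) == ["11"]

    def test_partial_dates_order_by_truncation(self):
        demo = parsed("DEMO", ["primaryid", "caseid", "fda_dt"],
                      [["11", "1", "2023"], ["12", "1", "202306"]])
        out = deduplicate_cases(demo)
        assert list(out["primaryid"]) == ["12"]

    @given(
        st.lists(
            st.tuples(
                st.integers(1, 5),       # caseid
                st.integers(1, 99),      # primaryid
                st.sampled_from(["20230101", "20230601", "20231231"]),
            ),
            min_size=1,
            max_size=25,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_case_conserving(self, raw_rows):
        rows = [[str(p), str(c), d] for c, p, d in raw_rows]
        # primaryid must be unique per FAERS semantics
        seen, uniq = set(), []
        for r in rows:
            if r[0] not in seen:
                seen.add(r[0])
                uniq.append(r)
        demo = parsed("DEMO", ["primaryid", "caseid", "fda_dt"], uniq)
        once = deduplicate_cases(demo)
        twice = deduplicate_cases(once)
        assert once.reset_index(drop=True).equals(twice.reset_index(drop=True))
        assert len(once) == demo.frame["caseid"].nunique()


class TestStandardizeDrugName:
    DICT = {
        "ENTRESTO": "SACUBITRIL/VALSARTAN",
        "SACUBITRIL AND VALSARTAN": "SACUBITRIL/VALSARTAN",
    }

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("entresto ", "SACUBITRIL/VALSARTAN"),
            ("SACUBITRIL AND VALSARTAN", "SACUBITRIL/VALSARTAN"),
            ("XYZZY", "XYZZY"),
            ("xyzzy", "XYZZY"),
        ],
    )
    def test_lookup(self, raw, expected):
        assert standardize_drug_name(raw, self.DICT) == expected


class TestLinkReports:
    def _tables(self):
        demo = parsed("DEMO", DEMO_HEADER,
                      [["11", "1", "20230105", "F", "70", "YR", "MD", "US", "20230101"]])
        drug = parsed("DRUG", ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "route"],
                      [["11", "1", "1", "PS", "Entresto", "ORAL"],
                       ["11", "1", "2", "C", "ASPIRIN", ""]])
        reac = parsed("REAC", ["primaryid", "caseid", "pt"],
                      [["11", "1", "Hypotension"], ["11", "1", "Cough"], ["11", "1", "Dizziness"]])
        return demo, drug, reac

    def test_join_arity(self):
        demo, drug, reac = self._tables()
        store = link_reports(demo, drug, reac,
                             drug_dictionary={"ENTRESTO": "SACUBITRIL/VALSARTAN"})
        assert store.n_reports == 1
        case = store.case("1")
        assert case.pts == {"Hypotension", "Cough", "Dizziness"}
        assert ("Entresto", "SACUBITRIL/VALSARTAN", "PS") in case.drugs
        assert case.route == "ORAL"
        assert case.age_years == 70.0

    def test_duplicate_pt_collapsed(self):
        demo, drug, _ = self._tables()
        reac = parsed("REAC", ["primaryid", "caseid", "pt"],
                      [["11", "1", "Hypotension"], ["11", "1", "Hypotension"]])
        store = link_reports(demo, drug, reac)
        assert list(store.report_pts["pt"]) == ["Hypotension"]

    def test_orphan_reac_counted(self):
        demo, drug, reac = self._tables()
        orphan = parsed("REAC", ["primaryid", "caseid", "pt"],
                        [["11", "1", "Cough"], ["999", "9", "Rash"]])
        store = link_reports(demo, drug, orphan)
        assert store.meta["n_orphan_reac_rows"] == 1
        assert "Rash" not in set(store.report_pts["pt"])

    def test_zero_reaction_report_dropped_and_counted(self):
        demo, drug, _ = self._tables()
        empty_reac = parsed("REAC", ["primaryid", "caseid", "pt"], [])
        store = link_reports(demo, drug, empty_reac)
        assert store.n_reports == 0
        assert store.meta["n_zero_reaction_reports"] == 1

    def test_outcome_codes_decoded(self):
        demo, drug, reac = self._tables()
        outc = parsed("OUTC", ["primaryid", "caseid", "outc_cod"],
                      [["11", "1", "HO"], ["11", "1", "DE"]])
        store = link_reports(demo, drug, reac, outc)
        assert store.case("1").outcomes == {"hospitalization", "death"}


class TestDates:
    @pytest.mark.parametrize(
        "raw, iso, precise",
        [
            ("20230415", "2023-04-15", True),
            ("202304", "2023-04-01", False),
            ("2023", "2023-01-01", False),
        ],
    )
    def test_parse_levels(self, raw, iso, precise):
        ts, prec = parse_faers_date(raw)
        assert str(ts.date()) == iso
        assert prec is precise

    @pytest.mark.parametrize("raw", ["", "garbage", "202313", None])
    def test_unparseable(self, raw):
        assert parse_faers_date(raw) is None


def test_store_round_trip(tmp_path, small_store):
    store, _ = small_store
    store.save(tmp_path / "store")
    from pvsignal.faers_io import ReportStore

    again = ReportStore.load(tmp_path / "store")
    assert store.equals(again)
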