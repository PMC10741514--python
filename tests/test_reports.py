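import random

import pytest
from hypothesis import given, strategies as st

from disprop.reports import (
    AdverseEventReport,
    DrugMention,
    DrugRole,
    FormatError,
    ReportSet,
    ValidationError,
    matches_term,
    normalize_drug_name,
    read_reports,
    write_reports,
)
from conftest import MFI, make_report
from oracle import random_report_set


class TestDataModel:
    def test_drug_name_normalized_uppercase_collapsed(self):
        m = DrugMention("  amlodipine   Besylate ", DrugRole.SUSPECT)
        assert m.drug_name == "AMLODIPINE BESYLATE"

    def test_empty_drug_name_rejected(self):
        with pytest.raises(ValidationError):
            DrugMention("   ", DrugRole.SUSPECT)

    def test_report_requires_a_suspect_drug(self):
        with pytest.raises(ValidationError, match="SUSPECT"):
            AdverseEventReport(
                "R1", (DrugMention("D1", DrugRole.CONCOMITANT),), ("Headache",)
            )

    @pytest.mark.parametrize("age", [-1, 131, 500])
    def test_age_outside_plausible_range_rejected(self, age):
        with pytest.raises(ValidationError, match="age"):
            make_report("R1", ["D1"], ["Rash"], age_years=age)

    def test_duplicate_report_ids_rejected_with_ids_listed(self):
        r1 = make_report("R1", ["D1"], ["Rash"])
        r2 = make_report("R1", ["D2"], [MFI])
        with pytest.raises(ValidationError) as err:
            ReportSet((r1, r2))
        assert "R1" in str(err.value)


class TestMatchesTerm:
    def test_case_insensitive_equality(self):
        r = make_report("R1", ["D1"], ["Infertility male"])
        assert matches_term(r, "infertility MALE")

    def test_related_term_is_not_a_match(self):
        # exact preferred-term equality: semen-parameter terms must not count
        r = make_report("R1", ["D1"], ["Oligozoospermia"])
        assert not matches_term(r, MFI)

    def test_membership_among_several_reactions(self):
        r = make_report("R1", ["D1"], [MFI, "Alopecia"])
        assert matches_term(r, MFI)

    @given(st.sampled_from([MFI, "Oligozoospermia", "Drug ineffective"]),
           st.booleans(), st.integers(0, 3))
    def test_invariant_under_case_and_whitespace(self, term, upper, pad):
        r = make_report("R1", ["D1"], [term])
        mangled = (" " * pad) + (term.upper() if upper else term.lower()) + (" " * pad)
        assert matches_term(r, mangled) == matches_term(r, term)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["CSV", "JSONL"])
    def test_write_read_identity_on_random_sets(self, fmt, tmp_path):
        rs = random_report_set(random.Random(7), n_max=100)
        path = tmp_path / f"reports.{fmt.lower()}"
        write_reports(rs, path, fmt)
        back = read_reports(path, fmt)
        assert len(back) == len(rs)
        assert back.reports == rs.reports  # field-by-field, order-preserving

    @pytest.mark.parametrize("fmt", ["CSV", "JSONL"])
    def test_empty_set_round_trips(self, fmt, tmp_path):
        path = tmp_path / f"empty.{fmt.lower()}"
        write_reports(ReportSet(()), path, fmt)
        if fmt == "CSV":
            assert path.read_text().startswith("report_id,")
        else:
            assert path.read_text() == ""
        assert len(read_reports(path, fmt)) == 0

    def test_multi_valued_cells_joined_with_pipe(self, tmp_path):
        rs = ReportSet((make_report("R1", ["D1", "D2"], [MFI]),))
        path = tmp_path / "one.csv"
        write_reports(rs, path, "CSV")
        assert "D1|D2" in path.read_text()

    def test_reasons_aligned_with_suspects(self, tmp_path):
        rs = ReportSet(
            (make_report("R1", ["D1", "D2"], [MFI], reasons={"D2": "alopecia"}),)
        )
        path = tmp_path / "reasons.csv"
        write_reports(rs, path, "CSV")
        back = read_reports(path, "CSV")
        assert back[0].reason_for("D2") == "alopecia"
        assert back[0].reason_for("D1") is None


class TestReadErrors:
    def test_three_row_csv_parses(self, tmp_path):
        path = tmp_path / "ok.csv"
        header = ("report_id,suspect_drugs,concomitant_drugs,reactions,reasons_for_use,"
                  "seriousness,event_year,sex,age_years,weight_kg,reporter_type,country,"
                  "has_literature_ref\n")
        rows = "".join(
            f"R{i},D{i},,Infertility male,,,,,,,CONSUMER,,false\n" for i in range(3)
        )
        path.write_text(header + rows)
        assert len(read_reports(path, "CSV")) == 3

    def test_duplicate_ids_in_file_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        header = ("report_id,suspect_drugs,concomitant_drugs,reactions,reasons_for_use,"
                  "seriousness,event_year,sex,age_years,weight_kg,reporter_type,country,"
                  "has_literature_ref\n")
        path.write_text(header + "R1,D1,,Rash,,,,,,,CONSUMER,,false\n" * 2)
        with pytest.raises(ValidationError, match="R1"):
            read_reports(path, "CSV")

    def test_missing_mandatory_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("report_id,suspect_drugs\nR1,D1\n")
        with pytest.raises(FormatError, match="reactions"):
            read_reports(path, "CSV")

    def test_zero_byte_file_is_empty_set(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert len(read_reports(path, "CSV")) == 0

    def test_invalid_rows_raise_or_skip(self, tmp_path):
        path = tmp_path / "mixed.csv"
        header = ("report_id,suspect_drugs,concomitant_drugs,reactions,reasons_for_use,"
                  "seriousness,event_year,sex,age_years,weight_kg,reporter_type,country,"
                  "has_literature_ref\n")
        good = "R1,D1,,Rash,,,,,,,CONSUMER,,false\n"
        bad = "R2,D2,,Rash,,,,,200,,CONSUMER,,false\n"  # impossible age
        path.write_text(header + good + bad)
        with pytest.raises(ValidationError, match="line 3"):
            read_reports(path, "CSV")
        rs = read_reports(path, "CSV", on_invalid="skip")
        assert [r.report_id for r in rs] == ["R1"]

    def test_accepted_rows_satisfy_invariants(self, tmp_path):
        # adversarial rows: whatever survives the reader obeys the data model
        path = tmp_path / "adv.csv"
        header = ("report_id,suspect_drugs,concomitant_drugs,reactions,reasons_for_use,"
                  "seriousness,event_year,sex,age_years,weight_kg,reporter_type,country,"
                  "has_literature_ref\n")
        rows = [
            "R1, d1 ,,  INFERTILITY   MALE ,,,,,44.5,,CONSUMER,us,true\n",
            "R2,,,Rash,,,,,,,CONSUMER,,false\n",          # no suspect drug
            "R3,D3,,,,,,,,,CONSUMER,,false\n",            # no reaction
            "R4,D4,,Rash,,,,,-3,,CONSUMER,,false\n",      # negative age
        ]
        path.write_text(header + "".join(rows))
        rs = read_reports(path, "CSV", on_invalid="skip")
        assert [r.report_id for r in rs] == ["R1"]
        r = rs[0]
        assert r.drugs[0].drug_name == "D1"
        assert r.reactions == ("infertility male",)
        assert r.country == "US" and r.has_literature_ref

    def test_generated_database_round_trips(self, masking_rs, tmp_path):
        sub = ReportSet(masking_rs.reports[:200], provenance="head")
        for fmt in ("CSV", "JSONL"):
            path = tmp_path / f"gen.{fmt.lower()}"
            write_reports(sub, path, fmt)
            assert read_reports(path, fmt).reports == sub.reports
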