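import random
from dataclasses import replace

import pytest
from hypothesis import given, strategies as st

from disprop.datasets import published_mfi_table
from disprop.simulate import generate_reports, recovery_scenario
from disprop.stats import (
    ContingencyTable,
    SignalCriteria,
    SignalTier,
    UndefinedEstimateError,
    build_contingency,
    classify_signal,
    compute_prr,
    compute_prr_ci,
    count_term_cases,
    filter_min_reports,
    run_primary_analysis,
)
from conftest import MFI, make_report
from oracle import naive_ci, naive_counts, naive_prr, naive_table, random_report_set
from disprop.reports import ReportSet


class TestCounting:
    def test_multi_suspect_report_counts_once_per_drug(self, toy_reports):
        # R1(D1), R2(D1+D2) match; R5(D3) matches; R3, R4 do not
        assert count_term_cases(toy_reports, MFI) == {"D1": 2, "D2": 1, "D3": 1}

    def test_no_match_gives_empty_mapping(self, toy_reports):
        assert count_term_cases(toy_reports, "Azoospermia") == {}

    def test_counts_match_bruteforce_on_synthetic_db(self):
        cfg = recovery_scenario(n_reports=10_000, seed=42)
        cfg.multi_suspect_prob = 0.3  # exercise the per-drug counting convention
        rs = generate_reports(cfg)
        assert count_term_cases(rs, cfg.index_term) == naive_counts(rs, cfg.index_term)


class TestInclusionFilter:
    def test_threshold_boundary_and_ordering(self):
        counts = {"X": 11, "Y": 10, "Z": 300}
        kept = filter_min_reports(counts, SignalCriteria(min_reports=11))
        assert kept == {"Z": 300, "X": 11}
        assert list(kept) == ["Z", "X"]  # descending count then name

    def test_empty_and_identity_cases(self):
        assert filter_min_reports({}, SignalCriteria()) == {}
        counts = {"A": 3, "B": 1}
        assert filter_min_reports(counts, SignalCriteria(min_reports=1)) == counts


class TestContingency:
    def test_enumerated_cells(self, toy_reports):
        t = build_contingency(toy_reports, "D1", MFI)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 1)

    def test_absent_drug_moves_all_term_reports_to_c(self, toy_reports):
        t = build_contingency(toy_reports, "D9", MFI)
        assert (t.a, t.b) == (0, 0)
        assert t.c == 3 and t.d == 2

    def test_cells_partition_random_sets(self):
        rng = random.Random(3)
        for _ in range(20):
            rs = random_report_set(rng, n_max=120)
            counts = count_term_cases(rs, MFI)
            n_term = sum(1 for r in rs if MFI.casefold() in r.reactions)
            for drug in counts:
                t = build_contingency(rs, drug, MFI)
                assert t.n == len(rs)
                assert t.a + t.c == n_term

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 1, 1)


class TestPRR:
    @pytest.mark.parametrize(
        "cells, expected",
        [((1, 9, 10, 90), 1.0), ((10, 90, 90, 9810), 11.0), ((0, 50, 100, 1000), 0.0)],
    )
    def test_point_estimate(self, cells, expected):
        assert compute_prr(ContingencyTable(*cells)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cells, cellname",
        [((0, 0, 5, 5), "A+B"), ((3, 7, 0, 10), "C"), ((3, 7, 0, 0), "C+D")],
    )
    def test_zero_cells_raise_named_errors(self, cells, cellname):
        with pytest.raises(UndefinedEstimateError, match=cellname.replace("+", r"\+")):
            compute_prr(ContingencyTable(*cells))

    def test_monotone_in_a_with_other_cells_fixed(self):
        prrs = [compute_prr(ContingencyTable(a, 50, 30, 900)) for a in range(1, 40)]
        assert all(x < y for x, y in zip(prrs, prrs[1:]))

    @given(st.integers(1, 200), st.integers(0, 200), st.integers(2, 6))
    def test_prr_is_one_for_equal_proportions(self, a, b, k):
        # (A, B) is an exact multiple of (C, D): the two proportions coincide
        t = ContingencyTable(a * k, b * k, a, b)
        assert compute_prr(t) == pytest.approx(1.0)


class TestConfidenceInterval:
    def test_worked_example(self):
        lo, hi = compute_prr_ci(ContingencyTable(10, 90, 90, 9810))
        assert lo == pytest.approx(5.90, abs=0.005)
        assert hi == pytest.approx(20.51, abs=0.005)

    def test_interval_brackets_estimate_and_straddles_one_when_balanced(self):
        t = ContingencyTable(50, 450, 500, 4500)
        prr = compute_prr(t)
        lo, hi = compute_prr_ci(t)
        assert lo < prr < hi
        assert lo < 1.0 < hi

    def test_halving_cells_widens_interval(self):
        rng = random.Random(11)
        for _ in range(30):
            a, b, c, d = (2 * rng.randint(1, 200) for _ in range(4))
            lo1, hi1 = compute_prr_ci(ContingencyTable(a, b, c, d))
            lo2, hi2 = compute_prr_ci(ContingencyTable(a // 2, b // 2, c // 2, d // 2))
            assert hi2 / lo2 > hi1 / lo1

    def test_zero_a_raises(self):
        with pytest.raises(UndefinedEstimateError):
            compute_prr_ci(ContingencyTable(0, 50, 100, 1000))

    def test_confidence_level_widens_with_level(self):
        t = ContingencyTable(10, 90, 90, 9810)
        lo95, hi95 = compute_prr_ci(t, SignalCriteria(confidence_level=0.95))
        lo99, hi99 = compute_prr_ci(t, SignalCriteria(confidence_level=0.99))
        assert lo99 < lo95 and hi99 > hi95


class TestClassification:
    @pytest.mark.parametrize(
        "prr, ci_low, tier",
        [
            (16.04, 12.67, SignalTier.STRONG),
            (1.72, 1.20, SignalTier.DISPROPORTIONATE),
            (1.07, 0.66, SignalTier.NONE),
            (0.51, 0.30, SignalTier.NONE),  # inverse association is not a signal
        ],
    )
    def test_published_rows(self, prr, ci_low, tier):
        assert classify_signal(prr, ci_low) is tier

    def test_flagged_partition_of_published_screen(self):
        df = published_mfi_table()
        tiers = [classify_signal(r.prr, r.ci_low) for r in df.itertuples()]
        flagged = {d for d, t in zip(df.drug, tiers) if t is not SignalTier.NONE}
        assert flagged == {
            "Finasteride",
            "Testosterone",
            "Valproic Acid",
            "Diethylstilbestrol",
            "Verapamil",
            "Nifedipine",
            "Mechlorethamine",
            "Lovastatin",
        }


class TestPrimaryAnalysis:
    def test_construction_fixes_number_of_results(self):
        reports = []
        i = 0
        for drug, n_mfi, n_other in [("A", 5, 2), ("B", 3, 1), ("C", 4, 0), ("D", 2, 9),
                                     ("E", 1, 1)]:
            for _ in range(n_mfi):
                reports.append(make_report(f"R{i}", [drug], [MFI])); i += 1
            for _ in range(n_other):
                reports.append(make_report(f"R{i}", [drug], ["Rash"])); i += 1
        rs = ReportSet(tuple(reports))
        res = run_primary_analysis(rs, MFI, SignalCriteria(min_reports=3))
        assert [r.drug_name for r in res] == ["A", "C", "B"]

    def test_unmatched_term_gives_empty_list(self, toy_reports):
        assert run_primary_analysis(toy_reports, "Azoospermia") == []

    def test_results_internally_consistent(self, masking_rs, masking_cfg):
        for res in run_primary_analysis(masking_rs, masking_cfg.index_term):
            assert res.ci_low <= res.prr <= res.ci_high
            assert res.signal_tier is classify_signal(res.prr, res.ci_low)
            assert res.n_cases == res.table.a >= SignalCriteria().min_reports

    def test_single_pass_cells_equal_per_drug_contingency(self):
        rng = random.Random(5)
        rs = random_report_set(rng, n_max=300)
        for res in run_primary_analysis(rs, MFI, SignalCriteria(min_reports=1)):
            assert res.table == build_contingency(rs, res.drug_name, MFI)

    def test_pipeline_matches_bruteforce_end_to_end(self, masking_rs, masking_cfg):
        res = run_primary_analysis(masking_rs, masking_cfg.index_term)
        assert res, "scenario must yield included drugs"
        for r in res:
            a, b, c, d = naive_table(masking_rs, r.drug_name, masking_cfg.index_term)
            assert (r.table.a, r.table.b, r.table.c, r.table.d) == (a, b, c, d)
            assert r.prr == pytest.approx(naive_prr(a, b, c, d), rel=1e-12)
            lo, hi = naive_ci(a, b, c, d)
            assert r.ci_low == pytest.approx(lo, rel=1e-12)
            assert r.ci_high == pytest.approx(hi, rel=1e-12)
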