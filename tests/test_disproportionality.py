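"""ROR arithmetic, 2x2 construction, signal criteria, ranking, expectedness."""
import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv import (
    ContingencyTable,
    SignalResult,
    build_contingency,
    classify_expectedness,
    comparator_background,
    cross_drug_overlap,
    ror,
    signal_criteria,
    top_terms,
)

cells = st.integers(1, 50)


def _result(term="x", n=5, ci_low=1.2, ci_high=9.0, ror_=3.0, significant=False,
            expectedness="not_significant"):
    return SignalResult(term=term, level="PT", n=n, ror=ror_, ci_low=ci_low,
                        ci_high=ci_high, significant=significant,
                        expectedness=expectedness)


class TestRor:
    def test_independence_table(self):
        est = ror(ContingencyTable(10, 10, 10, 10))
        assert est.ror == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_wald_formula_worked_example(self):
        est = ror(ContingencyTable(20, 80, 100, 9800))
        assert est.ror == pytest.approx(24.5)
        assert est.ci_low == pytest.approx(14.45, abs=0.01)
        assert est.ci_high == pytest.approx(41.55, abs=0.01)

    def test_sparse_table_wide_interval(self):
        est = ror(ContingencyTable(2, 998, 2, 8998))
        assert est.ror == pytest.approx(9.016, abs=1e-3)
        se = math.sqrt(1 / 2 + 1 / 998 + 1 / 2 + 1 / 8998)
        assert est.ci_low == pytest.approx(est.ror * math.exp(-1.959963984540054 * se))

    @pytest.mark.parametrize("table", [
        ContingencyTable(0, 10, 10, 10),
        ContingencyTable(10, 0, 10, 10),
        ContingencyTable(10, 10, 0, 10),
        ContingencyTable(10, 10, 10, 0),
    ])
    def test_zero_cell_incalculable(self, table):
        est = ror(table)
        assert est.incalculable
        assert math.isnan(est.ror)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=300, derandomize=True)
    def test_matches_exact_rational_odds_ratio(self, a, b, c, d):
        est = ror(ContingencyTable(a, b, c, d))
        oracle = Fraction(a * d, b * c)
        assert abs(est.ror - float(oracle)) <= 1e-12 * float(oracle)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=100, derandomize=True)
    def test_row_swap_inverts_estimate_and_bounds(self, a, b, c, d):
        fwd = ror(ContingencyTable(a, b, c, d))
        rev = ror(ContingencyTable(c, d, a, b))
        assert rev.ror == pytest.approx(1.0 / fwd.ror)
        assert rev.ci_low == pytest.approx(1.0 / fwd.ci_high)
        assert rev.ci_high == pytest.approx(1.0 / fwd.ci_low)

    @given(a=st.integers(1, 49), b=cells, c=cells, d=cells)
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_a(self, a, b, c, d):
        low = ror(ContingencyTable(a, b, c, d))
        high = ror(ContingencyTable(a + 1, b, c, d))
        assert high.ror > low.ror

    def test_wald_interval_matches_statsmodels(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        for a, b, c, d in [(20, 80, 100, 9800), (5, 7, 11, 13), (2, 998, 2, 8998)]:
            est = ror(ContingencyTable(a, b, c, d))
            t22 = sm_ct.Table2x2([[a, b], [c, d]])
            assert est.ror == pytest.approx(t22.oddsratio)
            lo, hi = t22.oddsratio_confint(alpha=0.05)
            assert est.ci_low == pytest.approx(lo)
            assert est.ci_high == pytest.approx(hi)


class TestBuildContingency:
    def test_exhaustive_ten_report_enumeration(self, report_factory):
        """2 cohort reports with PT x; 8 background, 3 with x; one PT each."""
        cohort = [report_factory(caseid=i, reactions=("x",)) for i in (1, 2)]
        background = (
            [report_factory(caseid=10 + i, reactions=("x",)) for i in range(3)]
            + [report_factory(caseid=20 + i, reactions=("y",)) for i in range(5)]
        )
        table = build_contingency(cohort, background, "x")
        assert (table.a, table.b, table.c, table.d) == (2, 0, 3, 5)
        assert table.n == 2

    def test_empty_cohort(self, report_factory):
        background = [report_factory(caseid=1, reactions=("x",))]
        table = build_contingency([], background, "x")
        assert (table.a, table.b) == (0, 0)

    def test_within_report_duplicate_pt_counts_once(self, report_factory):
        cohort = [report_factory(caseid=1, reactions=("x", "X", " x "))]
        table = build_contingency(cohort, [], "x")
        assert (table.a, table.b) == (1, 0)

    def test_pair_margin_counts_other_terms(self, report_factory):
        cohort = [report_factory(caseid=1, reactions=("x", "y", "z"))]
        table = build_contingency(cohort, [], "x")
        assert (table.a, table.b) == (1, 2)

    def test_soc_level_counts_once_per_soc(self, report_factory, fixture_map):
        # two PTs in the same SOC collapse to one SOC-level pair
        cohort = [report_factory(caseid=1, reactions=("alpha syndrome", "beta syndrome"))]
        table = build_contingency(cohort, [], "Nervous system disorders",
                                  level="SOC", meddra_map=fixture_map)
        assert (table.a, table.b) == (1, 0)

    def test_absent_term_flagged(self, report_factory):
        cohort = [report_factory(caseid=1, reactions=("y",))]
        table = build_contingency(cohort, [], "never reported")
        assert table.flagged_absent


class TestSignalCriteria:
    @pytest.mark.parametrize("ci_low, n, expected", [
        (1.2, 5, True),
        (1.2, 1, False),    # N >= 2 required
        (0.99, 100, False),
        (1.0, 100, False),  # strict inequality
        (float("nan"), 5, False),
    ])
    def test_rule(self, ci_low, n, expected):
        assert signal_criteria(_result(ci_low=ci_low, n=n)) is expected


class TestTopTerms:
    def _cohort(self, report_factory):
        reports = []
        cid = 0
        for term, count in (("alpha", 30), ("beta", 20), ("gamma", 10)):
            for _ in range(count):
                cid += 1
                reports.append(report_factory(caseid=cid, reactions=(term,)))
        return reports

    def _background(self, report_factory):
        return [report_factory(caseid=1000 + i, reactions=("other",)) for i in range(50)]

    def test_exclusion_then_rank_by_count(self, report_factory):
        results = top_terms(self._cohort(report_factory), self._background(report_factory),
                            k=2, exclusion=("gamma",))
        assert [r.term for r in results] == ["alpha", "beta"]
        assert [r.n for r in results] == [30, 20]

    def test_k_larger_than_term_count(self, report_factory):
        results = top_terms(self._cohort(report_factory), self._background(report_factory),
                            k=99)
        assert len(results) == 3

    def test_ties_broken_alphabetically(self, report_factory):
        cohort = ([report_factory(caseid=i, reactions=("zeta",)) for i in range(5)]
                  + [report_factory(caseid=10 + i, reactions=("eta",)) for i in range(5)])
        results = top_terms(cohort, self._background(report_factory), k=2)
        assert [r.term for r in results] == ["eta", "zeta"]


class TestExpectedness:
    def test_significant_on_label(self):
        results = classify_expectedness(
            [_result(term="vitamin a decreased", significant=True)],
            label_terms=["Vitamin A decreased"])
        assert results[0].expectedness == "labeled"

    def test_significant_off_label(self):
        results = classify_expectedness([_result(term="odd term", significant=True)], [])
        assert results[0].expectedness == "unexpected"

    def test_not_significant(self):
        results = classify_expectedness(
            [_result(term="vitamin a decreased", significant=False)],
            label_terms=["vitamin a decreased"])
        assert results[0].expectedness == "not_significant"


class TestCrossDrugOverlap:
    def test_pairwise_intersection(self):
        per_drug = {
            "A": [_result(term="x", significant=True, expectedness="unexpected"),
                  _result(term="y", significant=True, expectedness="unexpected")],
            "B": [_result(term="y", significant=True, expectedness="unexpected"),
                  _result(term="z", significant=True, expectedness="unexpected")],
        }
        labeled, unexpected = cross_drug_overlap(per_drug)
        assert unexpected == {"y"}
        assert labeled == set()

    def test_disjoint_sets_empty(self):
        per_drug = {
            "A": [_result(term="x", significant=True, expectedness="labeled")],
            "B": [_result(term="y", significant=True, expectedness="labeled")],
        }
        assert cross_drug_overlap(per_drug) == (set(), set())

    def test_identical_sets_returned(self):
        results = [_result(term="x", significant=True, expectedness="labeled")]
        per_drug = {"A": results, "B": results, "C": results}
        labeled, unexpected = cross_drug_overlap(per_drug)
        assert labeled == {"x"}


def test_comparator_background_excludes_cohort_by_default(report_factory):
    all_reports = [report_factory(caseid=i) for i in range(10)]
    cohort = all_reports[:3]
    background = comparator_background(all_reports, cohort)
    assert {r.caseid for r in background} == set(range(3, 10))
    assert len(comparator_background(all_reports, cohort, include_cohort=True)) == 10
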