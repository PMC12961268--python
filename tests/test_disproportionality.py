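"""ROR/IC arithmetic, signal criteria, unmasking and sex subgroups."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvfaers import (ContingencyTable, SignalEstimate, UnmaskingSpec,
                     assign_cohorts, build_contingency, compute_ic, compute_ror,
                     estimate_signal, evaluate_signal, run_unmasking,
                     sex_subgroup_analysis)
from pvfaers.cohorts import SUICIDE_SELF_INJURY

from conftest import make_drug, make_report

tables = st.tuples(st.integers(1, 500), st.integers(1, 500),
                   st.integers(1, 500), st.integers(1, 500))


class TestContingency:
    def test_cells_from_cohort_assignments(self):
        combo = [make_drug("semaglutide", "glp1ra", "PS"),
                 make_drug("metformin", "metformin", "C")]
        mono = [make_drug("semaglutide", "glp1ra", "PS")]
        reports = (
            [make_report(f"a{i}", drugs=combo, reactions=["Suicide attempt"])
             for i in range(3)]
            + [make_report(f"b{i}", drugs=combo) for i in range(7)]
            + [make_report(f"c{i}", drugs=mono, reactions=["Suicide attempt"])
               for i in range(5)]
            + [make_report(f"d{i}", drugs=mono) for i in range(85)])
        table = build_contingency(assign_cohorts(reports), "suicide_self_injury")
        assert table.cells() == (3, 7, 5, 85)
        assert table.a + table.b == 10 and table.c + table.d == 90

    def test_empty_cohort_is_an_error(self):
        reports = [make_report("1", reactions=["Suicide attempt"])]
        with pytest.raises(ValueError, match="empty cohort"):
            build_contingency(assign_cohorts(reports), "suicide_self_injury")

    def test_target_must_differ_from_comparator(self):
        with pytest.raises(ValueError):
            build_contingency({}, "x", "combination", "combination")

    def test_database_comparator_pools_all_other_reports(self):
        combo = [make_drug("semaglutide", "glp1ra", "PS"),
                 make_drug("metformin", "metformin", "C")]
        reports = ([make_report("1", drugs=combo, reactions=["Suicide attempt"])]
                   + [make_report("2")]
                   + [make_report("3", drugs=[make_drug("metformin",
                                                        "metformin", "PS")])])
        table = build_contingency(assign_cohorts(reports), "suicide_self_injury",
                                  comparator="database")
        assert table.cells() == (1, 0, 0, 2)

    def test_matches_generator_expected_counts(self, small_dataset,
                                               small_assignments):
        _, gt = small_dataset
        table = build_contingency(small_assignments, "suicide_self_injury")
        ea, eb, ec, ed = gt.expected_table("suicide_self_injury")
        # each cell within 5 binomial standard deviations of its expectation
        for observed, expected in zip(table.cells(), (ea, eb, ec, ed)):
            sd = math.sqrt(max(expected, 1.0))
            assert abs(observed - expected) < 5 * sd + 5


class TestRor:
    def test_reconstructed_cohort_totals_give_ror_3_49(self):
        ror, lo, hi, ok = compute_ror(ContingencyTable(104, 2530, 475, 40366))
        assert ok
        assert ror == pytest.approx(3.4933, abs=1e-3)
        assert lo == pytest.approx(2.8148, abs=1e-3)
        assert hi == pytest.approx(4.3354, abs=1e-3)

    def test_proportional_table_has_ror_one_with_ci_straddling(self):
        ror, lo, hi, ok = compute_ror(ContingencyTable(10, 90, 10, 90))
        assert ok and ror == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_zero_cell_is_non_estimable(self):
        *_, ok = compute_ror(ContingencyTable(0, 10, 5, 100))
        assert not ok

    @given(tables, st.integers(2, 9))
    @settings(deadline=None, max_examples=100)
    def test_ror_invariant_to_row_scaling_but_ic_is_not(self, cells, k):
        a, b, c, d = cells
        base = ContingencyTable(a, b, c, d)
        row_scaled = ContingencyTable(a * k, b * k, c, d)
        col_scaled = ContingencyTable(a * k, b, c * k, d)
        assert compute_ror(row_scaled)[0] == pytest.approx(compute_ror(base)[0])
        assert compute_ror(col_scaled)[0] == pytest.approx(compute_ror(base)[0])
        # the IC depends on the margins, not just the odds ratio
        ic_base = compute_ic(base, "plain")[0]
        ic_scaled = compute_ic(ContingencyTable(a * k, b * k, c * k, d), "plain")[0]
        assert ic_scaled != pytest.approx(ic_base, abs=1e-12)

    @given(tables, st.integers(2, 9))
    @settings(deadline=None, max_examples=100)
    def test_ci_width_shrinks_as_cells_scale_up(self, cells, k):
        a, b, c, d = cells
        _, lo1, hi1, _ = compute_ror(ContingencyTable(a, b, c, d))
        _, lo2, hi2, _ = compute_ror(ContingencyTable(a * k, b * k, c * k, d * k))
        assert math.log(hi2 / lo2) < math.log(hi1 / lo1)


class TestInformationComponent:
    def test_plain_ic_zero_on_proportional_table(self):
        ic, sd, ic025 = compute_ic(ContingencyTable(10, 90, 100, 900), "plain")
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert ic025 == pytest.approx(-2 * sd)

    def test_plain_ic_matches_direct_log2_evaluation(self):
        ic, _, _ = compute_ic(ContingencyTable(20, 80, 100, 900), "plain")
        assert ic == pytest.approx(0.874469, abs=1e-5)

    def test_plain_requires_positive_a(self):
        with pytest.raises(ValueError):
            compute_ic(ContingencyTable(0, 10, 5, 100), "plain")

    def test_shrinkage_defined_at_zero_cases(self):
        ic, sd, ic025 = compute_ic(ContingencyTable(0, 10, 5, 100), "shrinkage")
        assert sd is None and ic025 < ic < 0

    @given(tables)
    @settings(deadline=None, max_examples=200)
    def test_ic025_below_ic_for_both_methods(self, cells):
        table = ContingencyTable(*cells)
        for method in ("plain", "shrinkage"):
            ic, _, ic025 = compute_ic(table, method)
            assert ic025 < ic

    def test_shrinkage_converges_to_plain_for_large_counts(self):
        small = ContingencyTable(3, 7, 20, 170)
        big = ContingencyTable(30_000, 70_000, 200_000, 1_700_000)
        ic_plain = compute_ic(big, "plain")[0]
        ic_shrunk = compute_ic(big, "shrinkage")[0]
        assert ic_shrunk == pytest.approx(ic_plain, abs=1e-4)
        # shrinkage is material at small counts
        assert abs(compute_ic(small, "shrinkage")[0]
                   - compute_ic(small, "plain")[0]) > 1e-3


class TestSignalCriteria:
    def _estimate(self, a, ci_low, ic025):
        est = SignalEstimate(table=ContingencyTable(max(a, 1), 1, 1, 1),
                             n_cases=a, ror_ci_low=ci_low, ic025=ic025,
                             estimable=True)
        return est

    def test_fewer_than_three_cases_is_never_a_signal(self):
        assert not evaluate_signal(self._estimate(2, 2.0, 1.0))

    def test_all_three_criteria_met_is_a_signal(self):
        assert evaluate_signal(self._estimate(5, 1.01, 0.01))

    def test_ci_low_at_or_below_one_is_not_a_signal(self):
        assert not evaluate_signal(self._estimate(5, 0.99, 0.2))

    def test_ic025_at_or_below_zero_is_not_a_signal(self):
        assert not evaluate_signal(self._estimate(5, 1.5, 0.0))

    @given(st.tuples(st.integers(1, 50), st.integers(1, 200),
                     st.integers(1, 200), st.integers(1, 2000)))
    @settings(deadline=None, max_examples=100)
    def test_signal_is_monotone_in_case_count(self, cells):
        a, b, c, d = cells
        if evaluate_signal(estimate_signal(ContingencyTable(a, b, c, d))):
            bigger = estimate_signal(ContingencyTable(a + 5, b, c, d))
            assert evaluate_signal(bigger)


def _unmasking_fixture():
    """10 reports, 4 carrying a psychotropic concomitant.  After exclusion the
    cells are hand-computable on the remaining 6."""
    combo = [make_drug("semaglutide", "glp1ra", "PS"),
             make_drug("metformin", "metformin", "C")]
    mono = [make_drug("semaglutide", "glp1ra", "PS")]
    psych = make_drug("sertraline", "psychotropic", "C")
    reports = [
        make_report("1", drugs=combo, reactions=["Suicide attempt"]),
        make_report("2", drugs=combo + [psych], reactions=["Suicide attempt"]),
        make_report("3", drugs=combo),
        make_report("4", drugs=combo + [psych]),
        make_report("5", drugs=mono, reactions=["Suicide attempt"]),
        make_report("6", drugs=mono + [psych], reactions=["Suicide attempt"]),
        make_report("7", drugs=mono),
        make_report("8", drugs=mono),
        make_report("9", drugs=mono + [psych]),
        make_report("10", drugs=mono),
    ]
    return reports


class TestUnmasking:
    def test_no_excluded_drugs_is_a_no_op(self):
        reports = _unmasking_fixture()
        clean = [r for r in reports
                 if not any(d.class_tag == "psychotropic" for d in r.drugs)]
        assignments = assign_cohorts(clean)
        spec = UnmaskingSpec("x", frozenset({"psychotropic"}))
        base = estimate_signal(build_contingency(assignments,
                                                 "suicide_self_injury"))
        unmasked = run_unmasking(clean, assignments, spec, "suicide_self_injury")
        assert unmasked.table.cells() == base.table.cells()
        assert unmasked.ror == pytest.approx(base.ror)

    def test_hand_built_cells_after_exclusion(self):
        reports = _unmasking_fixture()
        assignments = assign_cohorts(reports)
        spec = UnmaskingSpec("x", frozenset({"psychotropic"}))
        est = run_unmasking(reports, assignments, spec, "suicide_self_injury")
        # remaining: combination {1 event, 1 non}, monotherapy {1 event, 3 non}
        assert est.table.cells() == (1, 1, 1, 3)
        assert est.ror == pytest.approx((1 * 3) / (1 * 1))

    def test_excluding_everything_is_non_estimable_with_reason(self):
        reports = _unmasking_fixture()
        assignments = assign_cohorts(reports)
        spec = UnmaskingSpec("x", frozenset({"glp1ra"}))  # every report has one
        est = run_unmasking(reports, assignments, spec, "suicide_self_injury")
        assert not est.estimable
        assert "empty cohort" in est.note

    def test_excluded_classes_must_be_non_empty(self):
        with pytest.raises(ValueError):
            UnmaskingSpec("x", frozenset())


def _subgroup_fixture(male_cells, female_cells):
    combo = [make_drug("semaglutide", "glp1ra", "PS"),
             make_drug("metformin", "metformin", "C")]
    mono = [make_drug("semaglutide", "glp1ra", "PS")]
    reports = []
    rid = 0
    for sex, (a, b, c, d) in (("M", male_cells), ("F", female_cells)):
        for drugs, n_event, n_non in ((combo, a, b), (mono, c, d)):
            for i in range(n_event):
                rid += 1
                reports.append(make_report(str(rid), sex=sex, drugs=drugs,
                                           reactions=["Suicidal behavior"]))
            for i in range(n_non):
                rid += 1
                reports.append(make_report(str(rid), sex=sex, drugs=drugs))
    return reports


class TestSexSubgroups:
    def test_ratio_equals_arithmetic_on_hand_built_strata(self):
        reports = _subgroup_fixture((6, 94, 10, 490), (3, 97, 10, 490))
        result = sex_subgroup_analysis(reports, assign_cohorts(reports),
                                       SUICIDE_SELF_INJURY,
                                       pts=["suicidal behavior"])
        ror_m = (6 * 490) / (94 * 10)
        ror_f = (3 * 490) / (97 * 10)
        assert result.ratios["suicidal behavior"] == pytest.approx(ror_m / ror_f)

    def test_identical_rates_in_both_sexes_give_ratio_one(self):
        reports = _subgroup_fixture((5, 95, 10, 490), (5, 95, 10, 490))
        result = sex_subgroup_analysis(reports, assign_cohorts(reports),
                                       SUICIDE_SELF_INJURY,
                                       pts=["suicidal behavior"])
        assert result.ratios["suicidal behavior"] == pytest.approx(1.0)

    def test_no_male_cases_gives_null_ratio(self):
        reports = _subgroup_fixture((0, 100, 10, 490), (3, 97, 10, 490))
        result = sex_subgroup_analysis(reports, assign_cohorts(reports),
                                       SUICIDE_SELF_INJURY,
                                       pts=["suicidal behavior"])
        assert result.ratios["suicidal behavior"] is None
        male = result.estimates.query("sex == 'M'")
        assert not male.estimable.item()

    def test_unknown_sex_reports_are_excluded_from_strata(self):
        reports = _subgroup_fixture((5, 95, 10, 490), (5, 95, 10, 490))
        reports.append(make_report("u1", sex="Unknown",
                                   reactions=["Suicidal behavior"]))
        result = sex_subgroup_analysis(reports, assign_cohorts(reports),
                                       SUICIDE_SELF_INJURY,
                                       pts=["suicidal behavior"])
        totals = result.estimates[["a", "b", "c", "d"]].to_numpy().sum()
        assert totals == 1200  # the Unknown-sex report is not counted
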