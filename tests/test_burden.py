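"""Interval intersection, exact Fisher test, and carrier-collapsing burden test."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from smmipkit import mipsim
from smmipkit.burden import (
    BurdenConfig,
    BurdenError,
    ContingencyTable2x2,
    burden_test,
    count_carriers,
    fisher_exact_two_sided,
    shared_covered_regions,
)


def fisher_oracle(a, b, c, d):
    """Brute-force two-sided Fisher by exact rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    ks = range(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in ks}
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs))


class TestSharedRegions:
    def test_simple_overlap(self):
        assert shared_covered_regions([("chr1", 0, 100)], [("chr1", 50, 150)]) == [
            ("chr1", 50, 100)
        ]

    def test_disjoint_is_empty(self):
        assert shared_covered_regions([("chr1", 0, 10)], [("chr1", 20, 30)]) == []
        assert shared_covered_regions([("chr1", 0, 10)], [("chr2", 0, 10)]) == []

    @given(
        st.lists(st.tuples(st.integers(0, 900), st.integers(1, 150)), max_size=10),
        st.lists(st.tuples(st.integers(0, 900), st.integers(1, 150)), max_size=10),
    )
    def test_matches_per_base_and_oracle(self, spans_a, spans_b):
        a = [("chrT", s, s + l) for s, l in spans_a]
        b = [("chrT", s, s + l) for s, l in spans_b]
        result = shared_covered_regions(a, b)
        in_a = np.zeros(1200, dtype=bool)
        in_b = np.zeros(1200, dtype=bool)
        for _, s, e in a:
            in_a[s:e] = True
        for _, s, e in b:
            in_b[s:e] = True
        from_result = np.zeros(1200, dtype=bool)
        for _, s, e in result:
            assert not from_result[s:e].any()
            from_result[s:e] = True
        assert (from_result == (in_a & in_b)).all()


class TestFisher:
    def test_no_carriers_anywhere_gives_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(0, 10, 0, 10)) == 1.0

    def test_hand_enumerated_three_outcome_case(self):
        """a=2,b=0,c=0,d=2: outcomes have probability 1/6, 4/6, 1/6 -> p = 1/3."""
        p = fisher_exact_two_sided(ContingencyTable2x2(2, 0, 0, 2))
        assert p == pytest.approx(1 / 3, rel=1e-12)

    def test_two_extreme_tables_of_252(self):
        """a=5,b=0,c=0,d=5: the two extreme tables each carry 1/252."""
        p = fisher_exact_two_sided(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / 252, rel=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(BurdenError):
            ContingencyTable2x2(-1, 2, 3, 4)

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
    def test_agrees_with_rational_oracle_and_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        table = ContingencyTable2x2(a, b, c, d)
        p = fisher_exact_two_sided(table)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)
        assert p == pytest.approx(
            stats.fisher_exact([[a, b], [c, d]]).pvalue, rel=1e-7
        )

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_invariant_under_row_and_column_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert fisher_exact_two_sided(ContingencyTable2x2(c, d, a, b)) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_two_sided(ContingencyTable2x2(d, c, b, a)) == pytest.approx(p, rel=1e-9)


def _cohort_tables(seed=5, case_freq=0.06, control_freq=0.05):
    cases, controls, truth = mipsim.simulate_cohort_tables(
        n_cases=373, n_controls=404,
        case_carrier_freq=case_freq, control_carrier_freq=control_freq, seed=seed,
    )
    return cases, controls, truth


class TestBurdenTest:
    def test_carrier_free_cohorts_not_significant(self):
        empty = pd.DataFrame(columns=mipsim.VARIANT_TABLE_COLUMNS)
        result = burden_test(empty, empty, 373, 404)
        assert result.p_value == 1.0
        assert not result.significant
        assert (result.table.a, result.table.c) == (0, 0)

    def test_carrier_collapsing_counts_each_patient_once(self):
        df = pd.DataFrame(
            {
                "patient_id": ["P1", "P1", "P2"],
                "classification": ["VUS", "VUS", "VUS"],
                "cadd": [25.0, 10.0, 30.0],
            }
        )
        assert count_carriers(df, "all") == 2
        assert count_carriers(df, "VUS") == 2
        assert count_carriers(df, "predicted_pathogenic") == 2

    def test_carrier_count_exceeding_cohort_is_contract_violation(self):
        df = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(5)], "classification": ["VUS"] * 5, "cadd": [25.0] * 5}
        )
        with pytest.raises(BurdenError, match="exceeds cohort size"):
            burden_test(df, df[0:0], 3, 100)

    def test_region_restriction_drops_uncovered_variants(self):
        df = pd.DataFrame(
            {
                "patient_id": ["P1", "P2"],
                "classification": ["VUS", "VUS"],
                "cadd": [25.0, 25.0],
                "chrom": ["chr1", "chr1"],
                "pos": [50, 500],
            }
        )
        regions = [("chr1", 0, 100)]
        assert count_carriers(df, "all", regions=regions) == 1

    def test_region_restriction_requires_coordinates(self):
        df = pd.DataFrame({"patient_id": ["P1"], "classification": ["VUS"], "cadd": [25.0]})
        with pytest.raises(BurdenError, match="chrom/pos"):
            count_carriers(df, "all", regions=[("chr1", 0, 10)])

    def test_observed_case_rate_vs_similar_controls_is_null(self):
        """22/373 cases vs a control cohort with a similar carrier rate: p > 0.05."""
        cases, controls, truth = _cohort_tables(seed=5)
        for stratum in ("all", "VUS"):
            result = burden_test(cases, controls, 373, 404, stratum)
            assert result.table.a == len(truth["case_carriers"])
            assert result.p_value > 0.05
            assert not result.significant

    def test_end_to_end_with_shared_regions(self):
        cases, controls, _ = _cohort_tables(seed=9)
        regions = shared_covered_regions([("chr11", 0, 10_000)], [("chr11", 0, 8_000)])
        result = burden_test(cases, controls, 373, 404, "all", shared_regions=regions)
        unrestricted = burden_test(cases, controls, 373, 404, "all")
        assert result.table.a <= unrestricted.table.a
        assert result.table.c <= unrestricted.table.c


def test_type_one_error_calibration_small():
    """Under equal carrier frequencies the test rejects at most ~alpha (60 seeds)."""
    rejections = 0
    n_sims = 60
    for seed in range(n_sims):
        cases, controls, _ = mipsim.simulate_cohort_tables(
            n_cases=373, n_controls=404,
            case_carrier_freq=0.05, control_carrier_freq=0.05, seed=seed,
        )
        result = burden_test(cases, controls, 373, 404, "all", BurdenConfig(alpha=0.05))
        rejections += result.significant
    assert rejections / n_sims <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)
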