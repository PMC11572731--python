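"""Group-comparison tests against enumeration oracles and scipy cross-checks."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from prl_mediation.errors import (ConfigurationError, DegenerateTableError,
                                  InsufficientDataError)
from prl_mediation.stats import (PlanItem, chi_square_2x2_cc, fisher_exact_2x2,
                                 rank_sum, table_one, table_one_frame,
                                 table_one_markdown, two_sample_t,
                                 two_sample_t_from_summary)


class TestChiSquare:
    def test_prl_prevalence_table_reproduces_published_p(self):
        # 55% of 117 BA and 39% of 123 WA patients with >= 1 PRL
        res = chi_square_2x2_cc([[64, 53], [48, 75]])
        assert res.p_value == pytest.approx(0.022, abs=0.002)
        # scipy computes the same Yates-corrected statistic here
        stat, p, _, _ = sps.chi2_contingency([[64, 53], [48, 75]], correction=True)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_balanced_table_has_zero_statistic(self):
        res = chi_square_2x2_cc([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_diagonal_table_matches_hand_computed_yates_value(self):
        # |ad - bc| = 25, n = 10: (25 - 5)^2 * 10 / 5^4 = 6.4
        res = chi_square_2x2_cc([[5, 0], [0, 5]])
        assert res.statistic == pytest.approx(6.4, rel=1e-12)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square_2x2_cc([[0, 0], [5, 5]])

    @given(st.lists(st.integers(25, 90), min_size=4, max_size=4))
    def test_agrees_with_fisher_in_significance_region(self, cells):
        """Yates-corrected chi-squared tracks the exact test closely where
        decisions are made; far from significance the two-sided Fisher
        p-value is discrete and the gap can reach ~0.1."""
        table = np.array(cells).reshape(2, 2)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        if expected.min() < 20:
            return
        chi = chi_square_2x2_cc(table)
        fis = fisher_exact_2x2(table)
        if min(chi.p_value, fis.p_value) <= 0.05:
            assert abs(chi.p_value - fis.p_value) < 0.02
        else:
            assert (chi.p_value > 0.05) and (fis.p_value > 0.05)


class TestTwoSampleT:
    def test_published_prl_percentage_row(self):
        # mean (SD) 8.01 (15.25) vs 3.40 (7.50), n = 117 / 123, Welch
        res = two_sample_t_from_summary(8.01, 15.25, 117, 3.40, 7.50, 123)
        assert res.statistic == pytest.approx(2.95, abs=0.02)
        assert 0.003 < res.p_value < 0.004

    def test_summary_entry_point_matches_raw_data(self, rng):
        x = rng.normal(1.0, 2.0, 40)
        y = rng.normal(0.4, 1.5, 55)
        raw = two_sample_t(x, y)
        summ = two_sample_t_from_summary(x.mean(), x.std(ddof=1), len(x),
                                         y.mean(), y.std(ddof=1), len(y))
        assert summ.statistic == pytest.approx(raw.statistic, rel=1e-10)
        assert summ.p_value == pytest.approx(raw.p_value, rel=1e-10)

    def test_identical_groups_give_t_zero_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = two_sample_t(x, x.copy())
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_pooled_equals_welch_for_equal_n_and_sd(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = x + 0.7  # same spread, shifted
        welch = two_sample_t(x, y, equal_var=False)
        pooled = two_sample_t(x, y, equal_var=True)
        assert welch.statistic == pytest.approx(pooled.statistic, rel=1e-12)
        assert welch.p_value == pytest.approx(pooled.p_value, rel=1e-12)

    def test_single_observation_rejected(self):
        with pytest.raises(InsufficientDataError):
            two_sample_t([1.0], [1.0, 2.0])


class TestRankSum:
    def test_fully_separated_small_groups_enumerate_to_one_twentieth(self):
        res = rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(2 * 1 / 20)

    def test_tied_singletons_give_p_one(self):
        res = rank_sum([5.0], [5.0])
        assert res.p_value == 1.0

    def test_approximation_close_to_exact_at_boundary(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.5, 1, 6)
            exact = rank_sum(x, y)                     # combined n = 12: exact
            approx = rank_sum(x, y, exact_limit=0)     # force normal path
            assert abs(exact.p_value - approx.p_value) < 0.02

    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_strictly_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=8)
        y = r.normal(0.3, 1.2, size=9)
        base = rank_sum(x, y)
        trans = rank_sum(np.exp(x), np.exp(y))  # strictly increasing map
        assert trans.p_value == pytest.approx(base.p_value, rel=1e-12)
        assert trans.statistic == pytest.approx(base.statistic, rel=1e-12)


class TestFisher:
    def test_against_hypergeometric_enumeration(self):
        table = np.array([[1, 9], [11, 3]])
        res = fisher_exact_2x2(table)
        # enumerate all tables with the observed margins
        n1, n2 = table.sum(1)
        c1 = table.sum(0)[0]
        obs_p = sps.hypergeom.pmf(table[0, 0], n1 + n2, c1, n1)
        total = sum(
            sps.hypergeom.pmf(a, n1 + n2, c1, n1)
            for a in range(max(0, c1 - n2), min(n1, c1) + 1)
            if sps.hypergeom.pmf(a, n1 + n2, c1, n1) <= obs_p * (1 + 1e-9))
        assert res.p_value == pytest.approx(total, rel=1e-9)
        assert res.p_value == pytest.approx(0.0028, abs=0.0002)

    def test_zero_row_uses_documented_p_one_convention(self):
        assert fisher_exact_2x2([[0, 0], [5, 5]]).p_value == 1.0

    def test_symmetric_table_is_uninformative(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]).p_value == 1.0


class TestTableOne:
    def test_default_plan_mirrors_characteristics_table(self, linear_cohort):
        results = table_one(linear_cohort)
        assert len(results) == 12
        assert all(0 <= r.p_value <= 1 for r in results)
        frame = table_one_frame(results)
        assert list(frame["variable"])[0].startswith("Male")
        assert "Percentage of PRL lesions" in " ".join(frame["variable"])

    def test_single_variable_plan(self, linear_cohort):
        results = table_one(linear_cohort, [PlanItem("age", "welch_t")])
        assert len(results) == 1
        assert results[0].test == "welch_t"

    def test_deterministic(self, linear_cohort):
        a = table_one_frame(table_one(linear_cohort))
        b = table_one_frame(table_one(linear_cohort))
        assert a.equals(b)

    def test_unknown_column_raises_plan_error(self, linear_cohort):
        with pytest.raises(ConfigurationError, match="unknown column"):
            table_one(linear_cohort, [PlanItem("karnofsky", "welch_t")])

    def test_markdown_rendering_contains_all_rows(self, linear_cohort):
        md = table_one_markdown(table_one(linear_cohort))
        assert md.count("\n") == 13  # header + rule + 12 rows
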