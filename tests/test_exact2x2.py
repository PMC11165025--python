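"""The exact conditional inference engine, checked against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact, hypergeom
from scipy.stats.contingency import odds_ratio as scipy_odds_ratio

from hlassoc.exact2x2 import (
    DegenerateTableError,
    NchgModel,
    associate_allele,
    cml_or,
    corrected_or,
    exact_ci,
    fisher_two_sided_p,
    nchg_pmf,
    result_from_table,
    screen_alleles,
)
from hlassoc.genotypes import ContingencyTable2x2, parse_allele

from conftest import make_cohort
from oracles import enum_fisher_p, grid_cml_or, random_tables

T = ContingencyTable2x2


class TestNchgModel:
    def test_central_limit_is_hypergeometric(self):
        model = NchgModel.from_table(T(3, 1, 11, 89))
        expected = hypergeom.pmf(model.support, model.N, model.K, model.n1)
        np.testing.assert_allclose(nchg_pmf(model, 1.0), expected, rtol=1e-12)

    def test_point_probability_example(self):
        # margins n1=4, K=14, N=104: C(14,3)*C(90,1)/C(104,4)
        model = NchgModel.from_table(T(3, 1, 11, 89))
        p3 = nchg_pmf(model, 1.0)[model.support == 3][0]
        assert p3 == pytest.approx(32760 / 4598126, rel=1e-12)

    @given(log_psi=st.floats(-6, 6))
    def test_pmf_normalised_for_any_psi(self, log_psi):
        model = NchgModel.from_table(T(2, 2, 50, 50))
        assert nchg_pmf(model, math.exp(log_psi)).sum() == pytest.approx(1.0)

    def test_nonpositive_psi_rejected(self):
        model = NchgModel.from_table(T(1, 1, 1, 1))
        with pytest.raises(ValueError):
            nchg_pmf(model, 0.0)
        with pytest.raises(ValueError):
            nchg_pmf(model, -2.0)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(DegenerateTableError):
            NchgModel.from_table(T(0, 0, 5, 5))
        with pytest.raises(DegenerateTableError):
            NchgModel.from_table(T(0, 4, 0, 100))

    def test_expected_count_increases_with_psi(self):
        rng = np.random.default_rng(11)
        for t in random_tables(rng, 20):
            model = NchgModel.from_table(T(*t))
            values = [model.expected(p) for p in (0.1, 0.5, 1.0, 3.0, 20.0)]
            assert all(x < y for x, y in zip(values, values[1:]))


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((3, 1, 11, 89), 7.34e-3),
            ((4, 0, 13, 87), 5.18e-4),
            ((1, 3, 10, 90), 0.3650),
            ((1, 3, 2, 98), 0.1120),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert fisher_two_sided_p(T(*table)) == pytest.approx(expected, rel=5e-3)

    def test_full_enumeration_oracle(self):
        t = T(2, 2, 50, 50)
        assert fisher_two_sided_p(t) == pytest.approx(
            float(enum_fisher_p(2, 2, 50, 50)), rel=1e-10
        )

    def test_random_tables_match_enumeration_and_scipy(self):
        rng = np.random.default_rng(2024)
        for t in random_tables(rng, 120):
            p = fisher_two_sided_p(T(*t))
            assert p == pytest.approx(float(enum_fisher_p(*t)), rel=1e-9), t
            p_scipy = fisher_exact([[t[0], t[1]], [t[2], t[3]]])[1]
            assert p == pytest.approx(p_scipy, rel=1e-7), t

    def test_degenerate_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            fisher_two_sided_p(T(0, 0, 3, 7))


class TestCmlOddsRatio:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((3, 1, 11, 89), 22.9),
            ((1, 3, 10, 90), 2.95),
            ((1, 3, 2, 98), 14.99),
        ],
    )
    def test_reference_values(self, table, expected):
        assert cml_or(T(*table)) == pytest.approx(expected, rel=5e-3)

    def test_balanced_table_is_one(self):
        assert cml_or(T(1, 1, 10, 10)) == pytest.approx(1.0, abs=1e-9)

    def test_grid_likelihood_oracle(self):
        assert cml_or(T(2, 2, 20, 80)) == pytest.approx(
            grid_cml_or(2, 2, 20, 80), rel=1e-6
        )

    def test_random_tables_match_scipy_conditional(self):
        rng = np.random.default_rng(7)
        for t in random_tables(rng, 40, positive_cells=True):
            ours = cml_or(T(*t))
            ref = scipy_odds_ratio(
                [[t[0], t[1]], [t[2], t[3]]], kind="conditional"
            ).statistic
            assert ours == pytest.approx(ref, rel=1e-6), t

    def test_row_swap_gives_reciprocal(self):
        rng = np.random.default_rng(13)
        for t in random_tables(rng, 30, positive_cells=True):
            table = T(*t)
            assert cml_or(table.swapped()) == pytest.approx(
                1.0 / cml_or(table), rel=1e-6
            ), t

    def test_support_boundaries_flagged(self):
        assert cml_or(T(4, 0, 13, 87)) == math.inf
        assert cml_or(T(0, 4, 13, 87)) == 0.0


class TestExactCI:
    def test_reference_interval(self):
        low, high = exact_ci(T(3, 1, 11, 89), alpha=0.05)
        assert low == pytest.approx(1.68, abs=5e-3)
        # the interval inverts the conditional tails exactly
        model = NchgModel.from_table(T(3, 1, 11, 89))
        assert model.upper_tail(3, low) == pytest.approx(0.025, abs=1e-9)
        assert model.lower_tail(3, high) == pytest.approx(0.025, abs=1e-9)

    def test_balanced_table_interval_contains_one(self):
        low, high = exact_ci(T(1, 1, 10, 10))
        assert low < 1.0 < high

    def test_boundary_counts_give_open_ends(self):
        low, high = exact_ci(T(4, 0, 13, 87))
        assert high == math.inf and low > 1.0
        low, high = exact_ci(T(0, 4, 13, 87))
        assert low == 0.0 and math.isfinite(high)
        # the finite bound still inverts the tail exactly
        model = NchgModel.from_table(T(0, 4, 13, 87))
        assert model.lower_tail(0, high) == pytest.approx(0.025, abs=1e-9)

    def test_tail_probabilities_reproduced_on_random_tables(self):
        rng = np.random.default_rng(99)
        for t in random_tables(rng, 30, positive_cells=True):
            table = T(*t)
            model = NchgModel.from_table(table)
            low, high = exact_ci(table, alpha=0.05)
            assert model.upper_tail(table.a, low) == pytest.approx(
                0.025, abs=1e-6
            ), t
            assert model.lower_tail(table.a, high) == pytest.approx(
                0.025, abs=1e-6
            ), t

    def test_estimate_inside_interval(self):
        rng = np.random.default_rng(3)
        for t in random_tables(rng, 25, positive_cells=True):
            table = T(*t)
            low, high = exact_ci(table)
            assert low <= cml_or(table) <= high, t

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            exact_ci(T(1, 1, 1, 1), alpha=1.5)


class TestCorrectedOr:
    def test_zero_cell_modes(self):
        t = T(4, 0, 13, 87)
        assert corrected_or(t, "zero_cells_only") == pytest.approx(
            4 * 87 / (0.5 * 13)
        )
        assert corrected_or(t, "all_cells") == pytest.approx(
            4.5 * 87.5 / (0.5 * 13.5)
        )

    def test_symmetric_table(self):
        assert corrected_or(T(1, 1, 1, 1), "zero_cells_only") == 1.0
        assert corrected_or(T(1, 1, 1, 1), "all_cells") == 1.0

    def test_no_correction_without_zero_cells(self):
        # plain cross-product (3.0) differs from the CML (2.95)
        assert corrected_or(T(1, 3, 10, 90), "zero_cells_only") == pytest.approx(3.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            corrected_or(T(1, 1, 1, 1), "half_everything")


class TestAssociate:
    def test_risk_allele_row(self, fx):
        r = associate_allele(fx.cohort, parse_allele("B*15:01"))
        assert r.table.as_tuple() == (3, 1, 11, 89)
        assert r.p_two_sided == pytest.approx(7.34e-3, rel=5e-3)
        assert r.or_estimate == pytest.approx(22.9, rel=5e-3)
        assert r.or_method == "cml"

    def test_zero_cell_table_uses_corrected_or(self):
        r = result_from_table("S140", T(4, 0, 13, 87))
        assert r.or_method == "corrected_cross_product"
        assert r.or_estimate == pytest.approx(53.5, rel=5e-3)

    def test_identical_proportions_are_null(self):
        rows = [("a", "case", "B*15:01", "B*07:02"),
                ("b", "case", "B*07:02", "B*07:02"),
                ("c", "tolerant_control", "B*15:01", "B*07:02"),
                ("d", "tolerant_control", "B*07:02", "B*07:02")]
        r = associate_allele(make_cohort(rows), parse_allele("B*15:01"))
        assert r.p_two_sided == 1.0
        assert r.or_estimate == pytest.approx(1.0, abs=1e-9)

    def test_universal_carrier_feature_is_null(self):
        r = result_from_table("x", T(4, 0, 100, 0))
        assert r.p_two_sided == 1.0
        assert r.ci_low == 0.0 and r.ci_high == math.inf


class TestScreen:
    def test_risk_allele_ranks_first(self, fx):
        results = screen_alleles(fx.cohort)
        assert results[0].feature == "B*15:01"
        ps = [r.p_two_sided for r in results]
        assert ps == sorted(ps)
        assert len(results) == 6  # one row per case-observed allele

    def test_two_sample_toy_is_null(self):
        rows = [("a", "case", "B*15:01", "B*13:01"),
                ("b", "tolerant_control", "B*15:01", "B*13:01")]
        results = screen_alleles(make_cohort(rows))
        assert all(r.p_two_sided == 1.0 for r in results)

    def test_no_case_alleles_gives_empty_list(self):
        rows = [("b", "tolerant_control", "B*15:01", "B*13:01")]
        assert screen_alleles(make_cohort(rows)) == []

    def test_bonferroni_annotation(self, fx):
        results = screen_alleles(fx.cohort, adjust="bonferroni")
        top = results[0]
        assert top.p_adjusted == pytest.approx(
            min(1.0, top.p_two_sided * len(results))
        )
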