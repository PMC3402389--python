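"""Inheritance-model collapsing, per-study odds ratios and HWE testing."""

import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from genemeta import (
    DegenerateTableError,
    GenotypeCounts,
    TwoByTwoTable,
    collapse,
    hwe_chi_square,
    hwe_exact,
    odds_ratio,
    swap_arms,
)

# Published control-arm HWE chi-square values for the 11-study table.
HWE_EXPECTED = [
    ((271, 538, 274), 0.045),
    ((164, 573, 408), 2.692),
    ((44, 207, 161), 3.563),
    ((161, 299, 122), 0.601),
    ((5, 47, 203), 1.310),
    ((52, 187, 182), 0.136),
    ((291, 711, 418), 0.128),
    ((199, 631, 530), 0.253),
    ((149, 598, 547), 0.562),
    ((51, 83, 25), 0.841),
    ((95, 151, 79), 1.525),
]

counts = st.tuples(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500)
).filter(lambda t: sum(t) > 0)

cells = st.tuples(
    st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500)
)


class TestCollapse:
    def test_additive_drops_heterozygotes(self):
        t = collapse("additive", GenotypeCounts(2, 20, 111), GenotypeCounts(5, 47, 203))
        assert (t.a, t.b, t.c, t.d) == (2, 111, 5, 203)
        assert not t.cc_applied

    def test_dominant_merges_carriers(self):
        t = collapse("dominant", GenotypeCounts(29, 65, 29), GenotypeCounts(51, 83, 25))
        assert (t.a, t.b, t.c, t.d) == (94, 29, 134, 25)

    def test_recessive_merges_t_carriers(self):
        t = collapse("recessive", GenotypeCounts(29, 65, 29), GenotypeCounts(51, 83, 25))
        assert (t.a, t.b, t.c, t.d) == (29, 94, 51, 108)

    def test_zero_cell_triggers_continuity_correction(self):
        t = collapse("dominant", GenotypeCounts(0, 0, 5), GenotypeCounts(0, 0, 5))
        assert t.cc_applied
        assert (t.a, t.b, t.c, t.d) == (0.5, 5.5, 0.5, 5.5)

    def test_empty_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            collapse("additive", GenotypeCounts(0, 10, 0), GenotypeCounts(5, 5, 5))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown inheritance model"):
            collapse("codominant", GenotypeCounts(1, 1, 1), GenotypeCounts(1, 1, 1))


class TestOddsRatio:
    def test_single_study_published_values(self):
        # African study: OR 0.73 (0.14-3.83) under the homozygote contrast
        est = odds_ratio(TwoByTwoTable(2, 111, 5, 203))
        assert round(est.or_, 2) == 0.73
        assert round(est.ci_low, 2) == 0.14
        assert round(est.ci_high, 2) == 3.83

    def test_balanced_table_is_null(self):
        est = odds_ratio(TwoByTwoTable(10, 10, 10, 10))
        assert est.log_or == 0
        assert est.or_ == 1.0
        assert est.ci_low == pytest.approx(1 / est.ci_high)

    def test_cross_product_arithmetic(self):
        est = odds_ratio(TwoByTwoTable(94, 29, 134, 25))
        assert est.or_ == pytest.approx(94 * 25 / (29 * 134), rel=1e-12)

    @given(cells)
    def test_ci_is_log_symmetric(self, abcd):
        est = odds_ratio(TwoByTwoTable(*abcd))
        upper = math.log(est.ci_high) - math.log(est.or_)
        lower = math.log(est.or_) - math.log(est.ci_low)
        assert upper == pytest.approx(lower, rel=1e-9)

    @given(cells, st.integers(2, 10))
    def test_scaling_cells_shrinks_se_by_sqrt_k(self, abcd, k):
        base = odds_ratio(TwoByTwoTable(*abcd))
        scaled = odds_ratio(TwoByTwoTable(*(k * x for x in abcd)))
        assert scaled.log_or == pytest.approx(base.log_or, abs=1e-9)
        assert scaled.se == pytest.approx(base.se / math.sqrt(k), rel=1e-9)


class TestSwapArms:
    @given(cells)
    def test_involution(self, abcd):
        t = TwoByTwoTable(*abcd)
        assert swap_arms(swap_arms(t)) == t

    @given(cells)
    def test_swap_inverts_odds_ratio(self, abcd):
        t = TwoByTwoTable(*abcd)
        assert odds_ratio(swap_arms(t)).or_ * odds_ratio(t).or_ == pytest.approx(
            1.0, rel=1e-9
        )

    @given(cells)
    def test_transposing_exposure_columns_inverts_odds_ratio(self, abcd):
        a, b, c, d = abcd
        orig = odds_ratio(TwoByTwoTable(a, b, c, d)).or_
        flipped = odds_ratio(TwoByTwoTable(b, a, d, c)).or_
        assert orig * flipped == pytest.approx(1.0, rel=1e-9)


class TestHWEChiSquare:
    @pytest.mark.parametrize("triple,expected", HWE_EXPECTED)
    def test_published_control_arms_to_three_decimals(self, triple, expected):
        res = hwe_chi_square(GenotypeCounts(*triple))
        assert round(res.chi2, 3) == expected

    def test_perfect_hwe_is_exactly_zero(self):
        res = hwe_chi_square(GenotypeCounts(25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.g_freq == 0.5

    def test_monomorphic_controls_flagged(self):
        res = hwe_chi_square(GenotypeCounts(0, 0, 50))
        assert res.monomorphic
        assert res.chi2 == 0.0

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            hwe_chi_square(GenotypeCounts(0, 0, 0))

    @given(counts)
    def test_allele_relabeling_symmetry(self, triple):
        gg, gt, tt = triple
        a = hwe_chi_square(GenotypeCounts(gg, gt, tt))
        b = hwe_chi_square(GenotypeCounts(tt, gt, gg))
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-9)


def _exact_oracle(gg, gt, tt):
    """Brute-force conditional HWE exact test with rational arithmetic."""
    n, n_g = gg + gt + tt, 2 * gg + gt
    weights = {}
    for h in range(n_g % 2, min(n_g, 2 * n - n_g) + 1, 2):
        ngg = (n_g - h) // 2
        ntt = n - ngg - h
        weights[h] = Fraction(
            math.factorial(n) * 2**h,
            math.factorial(ngg) * math.factorial(h) * math.factorial(ntt),
        )
    total = sum(weights.values())
    p_obs = weights[gt]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


class TestHWEExact:
    def test_modal_configuration_has_large_p(self):
        assert hwe_exact(GenotypeCounts(25, 50, 25)) > 0.5

    def test_extreme_heterozygote_deficit_matches_enumeration(self):
        assert hwe_exact(GenotypeCounts(5, 0, 5)) == pytest.approx(
            _exact_oracle(5, 0, 5), rel=1e-9
        )

    @given(
        st.tuples(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)).filter(
            lambda t: sum(t) > 0
        )
    )
    def test_matches_rational_oracle_and_stays_in_unit_interval(self, triple):
        p = hwe_exact(GenotypeCounts(*triple))
        assert 0 < p <= 1
        assert p == pytest.approx(_exact_oracle(*triple), rel=1e-9)
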