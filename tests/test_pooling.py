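"""Heterogeneity statistics and fixed/random pooled odds ratios."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genemeta import (
    EffectEstimate,
    TwoByTwoTable,
    cochran_q,
    odds_ratio,
    pool_fixed_mh,
    pool_random_dl,
    select_and_pool,
    z_test,
)

cells = st.tuples(
    st.integers(1, 300), st.integers(1, 300), st.integers(1, 300), st.integers(1, 300)
)
tables = st.lists(cells.map(lambda t: TwoByTwoTable(*t)), min_size=2, max_size=8)


def _est(log_or, se, sid=None):
    return EffectEstimate(
        study_id=sid,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - 1.959964 * se),
        ci_high=math.exp(log_or + 1.959964 * se),
    )


class TestCochranQ:
    def test_two_study_closed_form(self):
        # For two studies Q = (theta1 - theta2)^2 / (se1^2 + se2^2)
        het = cochran_q([_est(0.0, 0.1), _est(0.5, 0.1)])
        assert het.q == pytest.approx(12.5, rel=1e-12)
        assert het.df == 1

    def test_identical_estimates_have_no_dispersion(self):
        het = cochran_q([_est(0.3, 0.2)] * 3)
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0
        assert het.tau2 == 0.0

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cochran_q([_est(0.0, 0.1)])

    @given(
        st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.05, 1.0)), min_size=2, max_size=10
        )
    )
    def test_q_nonnegative_i2_bounded_tau2_nonnegative(self, params):
        het = cochran_q([_est(t, s) for t, s in params])
        assert het.q >= 0
        assert 0 <= het.i2 < 100
        assert het.tau2 >= 0


class TestMantelHaenszel:
    def test_single_study_equals_cross_product(self):
        t = TwoByTwoTable(94, 29, 134, 25)
        res = pool_fixed_mh([t])
        assert res.pooled_or == pytest.approx(odds_ratio(t).or_, rel=1e-12)
        assert res.method == "MH-fixed"

    def test_replicated_table_leaves_point_estimate_unchanged(self):
        t = TwoByTwoTable(20, 30, 15, 35)
        assert pool_fixed_mh([t, t]).pooled_or == pytest.approx(
            pool_fixed_mh([t]).pooled_or, rel=1e-12
        )

    @given(tables)
    def test_matches_rational_arithmetic_oracle(self, tabs):
        # Sum(ad/n) / Sum(bc/n) evaluated exactly with Fractions
        num = sum(Fraction(int(t.a) * int(t.d), int(t.n)) for t in tabs)
        den = sum(Fraction(int(t.b) * int(t.c), int(t.n)) for t in tabs)
        assert pool_fixed_mh(tabs).pooled_or == pytest.approx(
            float(num / den), rel=1e-10
        )

    @given(tables)
    def test_pooled_or_within_per_study_range(self, tabs):
        res = pool_fixed_mh(tabs)
        ors = [e.or_ for e in res.per_study]
        assert min(ors) - 1e-9 <= res.pooled_or <= max(ors) + 1e-9

    @given(tables, st.integers(2, 20))
    def test_scale_equivariance(self, tabs, k):
        res = pool_fixed_mh(tabs)
        scaled = pool_fixed_mh(
            [TwoByTwoTable(k * t.a, k * t.b, k * t.c, k * t.d) for t in tabs]
        )
        assert scaled.pooled_or == pytest.approx(res.pooled_or, rel=1e-9)
        assert scaled.ci_high - scaled.ci_low < res.ci_high - res.ci_low


class TestDerSimonianLaird:
    def test_zero_tau2_reduces_to_inverse_variance_fixed(self):
        ests = [_est(0.2, 0.1), _est(0.25, 0.2), _est(0.21, 0.15)]
        het = cochran_q(ests)
        assert het.tau2 == 0.0  # homogeneous by construction
        res = pool_random_dl(ests, het)
        w = [1 / e.se**2 for e in ests]
        iv = sum(wi * e.log_or for wi, e in zip(w, ests)) / sum(w)
        assert res.log_or == pytest.approx(iv, rel=1e-12)
        assert res.se == pytest.approx(1 / math.sqrt(sum(w)), rel=1e-12)

    def test_heterogeneity_widens_interval(self):
        homo = [_est(0.2, 0.1), _est(0.2, 0.1)]
        hetero = [_est(-0.5, 0.1), _est(0.9, 0.1)]
        r_homo = pool_random_dl(homo, cochran_q(homo))
        r_het = pool_random_dl(hetero, cochran_q(hetero))
        assert r_het.se > r_homo.se

    @given(
        st.lists(
            st.tuples(st.floats(-2, 2), st.floats(0.05, 1.0)), min_size=2, max_size=10
        )
    )
    def test_pooled_log_or_is_convex_combination(self, params):
        ests = [_est(t, s) for t, s in params]
        res = pool_random_dl(ests, cochran_q(ests))
        logs = [e.log_or for e in ests]
        assert min(logs) - 1e-9 <= res.log_or <= max(logs) + 1e-9
        assert res.weights == pytest.approx(
            tuple(w / sum(res.weights) for w in res.weights)
        )
        assert sum(res.weights) == pytest.approx(1.0, rel=1e-9)


class TestZTest:
    def test_null_identity(self):
        assert z_test(0.0, 0.5) == (0.0, pytest.approx(1.0))

    def test_quantile_identity(self):
        _, p = z_test(1.959964 * 0.3, 0.3)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_large_effect_matches_normal_tail_oracle(self):
        from scipy import stats

        z, p = z_test(0.565, 0.134)
        assert z == pytest.approx(0.565 / 0.134, rel=1e-12)
        assert round(z, 3) == 4.216
        assert p == pytest.approx(2 * stats.norm.sf(4.216418), rel=1e-4)
        assert p < 1e-4

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            z_test(0.1, 0.0)


class TestSelectAndPool:
    def test_homogeneous_studies_pool_fixed(self):
        t = TwoByTwoTable(50, 50, 40, 60)
        res = select_and_pool([t, t, t])
        assert res.method == "MH-fixed"
        assert res.het is not None and res.het.p > 0.1

    def test_heterogeneous_studies_pool_random(self):
        res = select_and_pool(
            [TwoByTwoTable(90, 10, 50, 50), TwoByTwoTable(10, 90, 50, 50)]
        )
        assert res.method == "DL-random"
        assert res.het.p <= 0.1

    def test_single_study_pools_fixed_with_heterogeneity_absent(self):
        t = TwoByTwoTable(2, 111, 5, 203)
        res = select_and_pool([t])
        assert res.method == "MH-fixed"
        assert res.het is None
        assert res.pooled_or == pytest.approx(odds_ratio(t).or_, rel=1e-12)

    def test_method_override_forces_choice(self):
        tabs = [TwoByTwoTable(50, 50, 40, 60)] * 3
        assert select_and_pool(tabs, method="random").method == "DL-random"
        assert select_and_pool(tabs, method="fixed").method == "MH-fixed"
        with pytest.raises(ValueError):
            select_and_pool(tabs, method="bayes")

    @given(tables)
    def test_ci_always_brackets_point_estimate(self, tabs):
        res = select_and_pool(tabs)
        assert res.ci_low <= res.pooled_or <= res.ci_high
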