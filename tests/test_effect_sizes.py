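"""Effect-size converters against independent hand-evaluated oracles.

Expected values below were computed by hand from the defining formulas
(pooled SD, J correction, delta-method variances) independently of the
implementation, and are asserted to at least six significant figures.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssmeta.effect_sizes import (
    g_from_chisq,
    g_from_f,
    g_from_proportions,
    g_from_summaries,
    g_from_t,
    hedges_j,
    lncvr,
    lnrr,
    lnvr,
)
from ssmeta.errors import DegenerateInputError, NotApplicableError, UnsupportedInputError
from ssmeta.records import GroupSummary

REL = 1e-7  # comfortably tighter than 6 significant figures


def gs(m, s, n):
    return GroupSummary(m=m, s=s, n=n)


class TestHedgesG:
    def test_summaries_hand_oracle(self):
        # d = 0.5/0.5 = 1 exactly; J = 1 - 3/151 = 148/151
        es = g_from_summaries(gs(1.5, 0.5, 20), gs(1.0, 0.5, 20))
        assert es.detail.d == pytest.approx(1.0, rel=1e-12)
        assert es.value == pytest.approx(148 / 151, rel=REL)
        j = 148 / 151
        assert es.variance == pytest.approx(j * j * (40 / 400 + 1.0 / 80), rel=REL)
        assert es.detail.df == 38

    def test_identical_groups_give_zero(self):
        es = g_from_summaries(gs(2.0, 0.4, 15), gs(2.0, 0.4, 15))
        assert es.value == 0.0

    def test_swap_negates_value_keeps_variance(self):
        a, b = gs(2.3, 0.7, 12), gs(1.8, 0.5, 17)
        e1, e2 = g_from_summaries(a, b), g_from_summaries(b, a)
        assert e1.value == pytest.approx(-e2.value, rel=1e-12)
        assert e1.variance == pytest.approx(e2.variance, rel=1e-12)

    def test_zero_pooled_sd_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            g_from_summaries(gs(1.0, 0.0, 10), gs(2.0, 0.0, 10))

    def test_t_hand_oracle(self):
        # d = 2 sqrt(40/400) = 0.6324555...; g = d * 148/151
        es = g_from_t(2.0, 20, 20)
        d = 2.0 * math.sqrt(40 / 400)
        assert es.detail.d == pytest.approx(d, rel=REL)
        assert es.value == pytest.approx(d * 148 / 151, rel=REL)

    def test_t_zero(self):
        assert g_from_t(0.0, 10, 10).value == 0.0

    def test_t_matches_summaries_on_same_groups(self):
        # converting summaries to t and back must agree to 6+ sig figs
        a, b = gs(5.1, 1.2, 24), gs(4.4, 1.0, 24)
        direct = g_from_summaries(a, b)
        sp = math.sqrt(((a.n - 1) * a.s**2 + (b.n - 1) * b.s**2) / (a.n + b.n - 2))
        t = (a.m - b.m) / (sp * math.sqrt(1 / a.n + 1 / b.n))
        via_t = g_from_t(t, a.n, b.n)
        assert via_t.value == pytest.approx(direct.value, rel=1e-9)
        assert via_t.variance == pytest.approx(direct.variance, rel=1e-9)

    def test_f_equals_squared_t_route(self):
        via_t = g_from_t(2.0, 20, 20)
        via_f = g_from_f(4.0, 20, 20, direction=1)
        assert via_f.value == pytest.approx(via_t.value, rel=1e-12)
        with pytest.raises(ValueError):
            g_from_f(-1.0, 20, 20)

    def test_chisq_hand_oracle(self):
        # r = sqrt(3.84/100); d = 2r / sqrt(1-r^2) = 0.3996503...
        es = g_from_chisq(3.84, 100, direction=1)
        r = math.sqrt(0.0384)
        d = 2 * r / math.sqrt(1 - 0.0384)
        assert d == pytest.approx(0.400, abs=5e-4)
        assert es.detail.d == pytest.approx(d, rel=REL)
        assert es.value == pytest.approx(d * hedges_j(98), rel=REL)

    def test_chisq_df_above_one_unsupported(self):
        with pytest.raises(UnsupportedInputError):
            g_from_chisq(5.0, 100, df=2)

    def test_proportion_continuity_rule(self):
        # p_high = 1 -> numerator reduced by one: (n-1)/n before logit
        n = 25
        es = g_from_proportions(1.0, 0.5, n, n)
        ph = (n - 1) / n
        d = (math.log(ph / (1 - ph)) - 0.0) / 1.65
        assert es.detail.d == pytest.approx(d, rel=REL)

    def test_proportion_boundary_without_count_errors(self):
        with pytest.raises(DegenerateInputError):
            g_from_proportions(0.0, 0.5, None, 20)


class TestRatioMeasures:
    def test_lnrr_hand_oracle(self):
        es = lnrr(gs(2.0, 0.5, 10), gs(1.0, 0.5, 10))
        assert es.value == pytest.approx(math.log(2), rel=REL)
        assert es.variance == pytest.approx(0.03125, rel=REL)

    def test_lnrr_equal_means_zero_and_swap_negates(self):
        assert lnrr(gs(3.0, 0.4, 9), gs(3.0, 0.6, 11)).value == 0.0
        a, b = gs(2.0, 0.5, 10), gs(1.5, 0.4, 13)
        assert lnrr(a, b).value == pytest.approx(-lnrr(b, a).value, rel=1e-12)

    def test_lnrr_nonpositive_mean_not_applicable(self):
        with pytest.raises(NotApplicableError):
            lnrr(gs(-1.0, 0.5, 10), gs(1.0, 0.5, 10))

    def test_lncvr_hand_oracle(self):
        # CV_h = 0.1, CV_l = 0.2 -> ln 0.5
        es = lncvr(gs(2.0, 0.2, 20), gs(1.0, 0.2, 20))
        assert es.value == pytest.approx(math.log(0.5), rel=REL)
        # variance oracle: s=(0.2,0.3), m=(2,1.5), n=(20,20), rho=0
        es2 = lncvr(gs(2.0, 0.2, 20), gs(1.5, 0.3, 20))
        expected = 0.04 / (20 * 4) + 1 / 38 + 0.09 / (20 * 2.25) + 1 / 38
        assert expected == pytest.approx(0.05513, abs=5e-6)
        assert es2.variance == pytest.approx(expected, rel=REL)

    def test_lncvr_identical_groups_zero(self):
        assert lncvr(gs(2.0, 0.4, 15), gs(2.0, 0.4, 15)).value == 0.0

    def test_lncvr_rho_reduces_variance(self):
        a, b = gs(2.0, 0.2, 20), gs(1.5, 0.3, 20)
        assert lncvr(a, b, rho=0.5).variance < lncvr(a, b, rho=0.0).variance

    def test_lnvr_hand_oracle(self):
        es = lnvr(gs(4.0, 2.0, 10), gs(4.0, 1.0, 10))
        assert es.value == pytest.approx(math.log(2), rel=REL)
        assert es.variance == pytest.approx(1 / 9, rel=REL)

    def test_lnvr_equal_sd_equal_n_exactly_zero(self):
        assert lnvr(gs(3.0, 1.1, 14), gs(5.0, 1.1, 14)).value == 0.0

    def test_lnvr_swap_equal_n_negates(self):
        a, b = gs(4.0, 2.0, 10), gs(3.0, 1.3, 10)
        assert lnvr(a, b).value == pytest.approx(-lnvr(b, a).value, rel=1e-12)

    def test_zero_sd_not_applicable(self):
        with pytest.raises(NotApplicableError):
            lnvr(gs(4.0, 0.0, 10), gs(4.0, 1.0, 10))
        with pytest.raises(NotApplicableError):
            lncvr(gs(4.0, 0.0, 10), gs(4.0, 1.0, 10))


@st.composite
def group_pairs(draw):
    m1 = draw(st.floats(0.5, 50))
    m2 = draw(st.floats(0.5, 50))
    s1 = draw(st.floats(0.05, 10))
    s2 = draw(st.floats(0.05, 10))
    n = draw(st.integers(3, 500))
    return gs(m1, s1, n), gs(m2, s2, n)


class TestProperties:
    @given(group_pairs())
    @settings(max_examples=100, deadline=None)
    def test_equal_n_antisymmetry_all_measures(self, pair):
        a, b = pair
        for fn in (g_from_summaries, lnrr, lncvr, lnvr):
            fwd, rev = fn(a, b), fn(b, a)
            assert fwd.value == pytest.approx(-rev.value, rel=1e-9, abs=1e-12)
            assert fwd.variance == pytest.approx(rev.variance, rel=1e-9)

    @given(st.integers(3, 200))
    @settings(max_examples=50, deadline=None)
    def test_variance_decreases_with_group_size(self, n):
        a, b = gs(2.0, 0.5, n), gs(1.5, 0.5, n)
        a2, b2 = gs(2.0, 0.5, 2 * n), gs(1.5, 0.5, 2 * n)
        for fn in (g_from_summaries, lnrr, lncvr, lnvr):
            assert fn(a2, b2).variance < fn(a, b).variance

    @given(st.integers(2, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_j_correction_in_unit_interval(self, df):
        assert 0.0 < hedges_j(df) < 1.0
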