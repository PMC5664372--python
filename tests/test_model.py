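"""Closed-form model components: frozen examples, domain errors, invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icdpower import (
    CodeAttrition,
    CohortSpec,
    DesignQuery,
    GeneticArchitecture,
    case_allele_frequency,
    case_count,
    effective_allele_sample,
    evaluate_design,
    misclassification_fraction,
    noncentrality,
    power,
)

# strategies over admissible parameter space
q_st = st.floats(0.01, 0.5)
R_st = st.floats(0.2, 5.0).filter(lambda r: abs(r - 1.0) > 1e-3)
delta_st = st.floats(0.01, 0.9)
eps_st = st.floats(0.0, 0.9)
x_st = st.floats(0.0, 30.0)


class TestMisclassificationFraction:
    @pytest.mark.parametrize(
        "delta, x, expected",
        [
            (0.15, 0.0, 1.0),
            (0.15, 1.0, 0.85),
            (0.15, 7.0, 0.3205770882812499),
        ],
    )
    def test_values(self, delta, x, expected):
        att = CodeAttrition(delta=delta, epsilon=0.1)
        assert misclassification_fraction(att, x) == pytest.approx(expected, rel=1e-12)

    def test_negative_x_rejected(self, attrition):
        with pytest.raises(ValueError):
            misclassification_fraction(attrition, -0.5)

    @given(delta=delta_st, x=st.floats(0.1, 20.0), dx=st.floats(0.1, 5.0))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing(self, delta, x, dx):
        att = CodeAttrition(delta=delta, epsilon=0.1)
        assert misclassification_fraction(att, x + dx) < misclassification_fraction(att, x)


class TestCaseCount:
    @pytest.mark.parametrize(
        "n1, eps, x, expected",
        [
            (400.0, 0.15, 0.0, 400.0),
            (400.0, 0.0, 9.0, 400.0),
            (400.0, 0.15, 7.0, 150.37481596923706),
        ],
    )
    def test_values(self, n1, eps, x, expected):
        c = CohortSpec(n1=n1, m=10_000)
        assert case_count(c, CodeAttrition(0.15, eps), x) == pytest.approx(expected, rel=1e-12)

    def test_negative_x_rejected(self, cohort, attrition):
        with pytest.raises(ValueError):
            case_count(cohort, attrition, -1.0)

    @given(eps=st.floats(0.01, 0.9), x=st.floats(0.0, 20.0), dx=st.floats(0.1, 5.0))
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing_for_positive_epsilon(self, eps, x, dx):
        c = CohortSpec(n1=500.0, m=1000.0)
        att = CodeAttrition(0.1, eps)
        assert case_count(c, att, x + dx) < case_count(c, att, x)


class TestCaseAlleleFrequency:
    @pytest.mark.parametrize(
        "q, R, f, expected",
        [
            (0.2, 2.0, 1.0, 0.2),  # fully misclassified cases are population draws
            (0.2, 1.0, 0.37, 0.2),  # null variant: s = q for any purity
            (0.2, 2.0, 0.0, 1.0 / 3.0),  # pure cases: Rq/(1+(R-1)q)
            (0.2, 2.0, 0.3205770882812499, 0.2905897215625),
        ],
    )
    def test_values(self, q, R, f, expected):
        assert case_allele_frequency(GeneticArchitecture(q, R), f) == pytest.approx(
            expected, rel=1e-12
        )

    def test_f_out_of_range_rejected(self, gen):
        with pytest.raises(ValueError):
            case_allele_frequency(gen, 1.2)

    @given(q=q_st, R=R_st, f=st.floats(0.0, 1.0))
    @settings(max_examples=100, derandomize=True)
    def test_s_bounded_between_q_and_true_case_frequency(self, q, R, f):
        g = GeneticArchitecture(q, R)
        s = case_allele_frequency(g, f)
        lo, hi = sorted([q, g.true_case_frequency])
        assert lo - 1e-12 <= s <= hi + 1e-12


class TestEffectiveAlleleSample:
    def test_equal_groups_give_two_n(self):
        assert effective_allele_sample(500.0, 500.0) == pytest.approx(1000.0)

    def test_baseline_point(self):
        assert effective_allele_sample(150.374, 10_000.0) == pytest.approx(592.585, abs=5e-3)

    def test_large_control_limit(self):
        assert effective_allele_sample(100.0, 1e12) == pytest.approx(400.0, rel=1e-6)

    def test_symmetric(self):
        assert effective_allele_sample(123.0, 4567.0) == effective_allele_sample(4567.0, 123.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            effective_allele_sample(0.0, 10.0)


class TestNoncentrality:
    def test_zero_iff_equal_frequencies(self):
        assert noncentrality(0.2, 0.2, 1234.0) == 0.0
        assert noncentrality(0.2, 0.21, 1234.0) > 0.0

    def test_baseline_pure_case_value(self):
        assert noncentrality(0.2, 1.0 / 3.0, 592.59) == pytest.approx(27.5623, abs=1e-3)

    @given(q=q_st, s=st.floats(0.01, 0.99), N=st.floats(10.0, 1e5))
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_and_nonnegative(self, q, s, N):
        a = noncentrality(q, s, N)
        assert a >= 0.0
        assert a == pytest.approx(noncentrality(s, q, N), rel=1e-12)

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            noncentrality(0.0, 0.5, 100.0)


class TestPower:
    def test_zero_ncp_gives_half_alpha(self):
        assert power(0.0, 0.05) == pytest.approx(0.025, abs=1e-12)
        assert power(0.0, 0.01) == pytest.approx(0.005, abs=1e-12)

    def test_ncp_equal_squared_critical_value_gives_half(self):
        from scipy.stats import norm

        for alpha in (0.05, 0.01, 0.2):
            z = float(norm.ppf(1 - alpha / 2))
            assert power(z * z, alpha) == pytest.approx(0.5, abs=1e-12)

    def test_large_ncp(self):
        assert power(27.56, 0.05) == pytest.approx(0.9994987031997998, rel=1e-10)

    def test_negative_ncp_rejected(self):
        with pytest.raises(ValueError):
            power(-1.0, 0.05)

    @given(ncp=st.floats(0.0, 50.0), dn=st.floats(0.1, 10.0), alpha=st.floats(0.001, 0.2))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_ncp(self, ncp, dn, alpha):
        assert power(ncp + dn, alpha) > power(ncp, alpha)


class TestEvaluateDesign:
    def test_baseline_point_fields(self, gen, cohort, attrition):
        pt = evaluate_design(gen, cohort, attrition, DesignQuery(x=7.0, alpha=0.05))
        assert pt.f == pytest.approx(0.320577, abs=1e-6)
        assert pt.n_x == pytest.approx(150.374, abs=1e-3)
        assert pt.s == pytest.approx(0.290590, abs=1e-6)
        assert pt.N == pytest.approx(592.59, abs=5e-3)
        assert pt.ncp == pytest.approx(13.281740556439331, rel=1e-10)

    def test_null_variant_power_is_half_alpha(self, cohort, attrition):
        null = GeneticArchitecture(q=0.2, R=1.0)
        for x in (1.0, 5.0, 12.0):
            pt = evaluate_design(null, cohort, attrition, DesignQuery(x=x, alpha=0.05))
            assert pt.power == pytest.approx(0.025, abs=1e-12)

    def test_total_decay_gives_pure_case_frequency(self, gen, cohort):
        att = CodeAttrition(delta=1.0 - 1e-12, epsilon=0.15)
        pt = evaluate_design(gen, cohort, att, DesignQuery(x=5.0))
        assert pt.s == pytest.approx(gen.true_case_frequency, rel=1e-9)

    @given(q=q_st, R=R_st, delta=delta_st, eps=eps_st, x=x_st)
    @settings(max_examples=100, derandomize=True)
    def test_equals_manual_composition(self, q, R, delta, eps, x):
        g = GeneticArchitecture(q, R)
        c = CohortSpec(400.0, 10_000.0)
        a = CodeAttrition(delta, eps)
        pt = evaluate_design(g, c, a, DesignQuery(x=x, alpha=0.05))
        f = misclassification_fraction(a, x)
        n_x = case_count(c, a, x)
        s = case_allele_frequency(g, f)
        N = effective_allele_sample(n_x, c.m)
        assert pt.f == f and pt.n_x == n_x and pt.s == s and pt.N == N
        assert pt.ncp == noncentrality(q, s, N)
        assert pt.power == power(pt.ncp, 0.05)


class TestDomainValidation:
    @pytest.mark.parametrize(
        "ctor, kwargs",
        [
            (GeneticArchitecture, {"q": 0.0, "R": 2.0}),
            (GeneticArchitecture, {"q": 1.0, "R": 2.0}),
            (GeneticArchitecture, {"q": 0.2, "R": -1.0}),
            (CohortSpec, {"n1": 0.0, "m": 100.0}),
            (CohortSpec, {"n1": 100.0, "m": -5.0}),
            (CodeAttrition, {"delta": 0.0, "epsilon": 0.1}),
            (CodeAttrition, {"delta": 1.0, "epsilon": 0.1}),
            (CodeAttrition, {"delta": 0.1, "epsilon": -0.1}),
            (DesignQuery, {"x": -1.0}),
            (DesignQuery, {"x": 3.0, "alpha": 0.0}),
        ],
    )
    def test_invalid_construction_rejected(self, ctor, kwargs):
        with pytest.raises(ValueError):
            ctor(**kwargs)
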