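"""Exact Picard engine: frozen worked-example coefficients, a sympy
integration oracle, and algebraic property tests."""

from fractions import Fraction

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import operanteq as oq
from operanteq import (
    RationalPolynomial,
    coefficient_query,
    evaluate_poly,
    picard_iterates,
    picard_step_exact,
    poly_compose_affine,
)
from operanteq.model import make_affine_operator

# -- frozen coefficients of the printed worked examples ----------------------

GAMMA1_EX1 = {1: Fraction(2, 5), 2: Fraction(1, 40), 3: Fraction(1, 60)}
GAMMA2_EX1 = {
    1: Fraction(619, 3750),
    2: Fraction(3577, 320000),
    3: Fraction(3217, 480000),
    4: Fraction(13, 76800),
    5: Fraction(61, 2400000),
}
GAMMA3_EX1_TOP = {
    5: Fraction(39825883, 3840000000000),
    6: Fraction(1694537, 23040000000000),
    7: Fraction(128161, 53760000000000),
}
GAMMA1_EX2 = {1: Fraction(1, 5), 2: Fraction(1, 10)}
# the quadratic coefficient is the exactly-integrated 3/125, not the
# misprinted 6/750 of the displayed final line
GAMMA2_EX2 = {1: Fraction(11, 250), 2: Fraction(3, 125), 3: Fraction(1, 750)}


def _to_sympy(poly: RationalPolynomial, var):
    return sum(sp.Rational(c.numerator, c.denominator) * var**k for k, c in poly.coeffs.items())


def _sympy_picard_step(model, expr, x, t):
    integrand = sp.Integer(0)
    for w, op in model.terms:
        wexpr = sum(
            sp.Rational(c.numerator, c.denominator) * x**i * t**j
            for (i, j), c in w.coeffs.items()
        )
        oexpr = sp.Rational(op.slope.numerator, op.slope.denominator) * t + sp.Rational(
            op.intercept.numerator, op.intercept.denominator
        )
        integrand += wexpr * expr.subs(x, oexpr)
    return sp.integrate(sp.expand(integrand), (t, 0, x)).expand()


class TestWorkedExampleIterates:
    def test_two_choice_first_iterate(self, example1_trace):
        assert dict(example1_trace.iterates[1].coeffs) == GAMMA1_EX1

    def test_two_choice_second_iterate_all_coefficients(self, example1_trace):
        assert dict(example1_trace.iterates[2].coeffs) == GAMMA2_EX1

    def test_two_choice_third_iterate_leading_coefficients(self, example1_trace):
        g3 = example1_trace.iterates[3]
        assert g3.degree == 7
        for k, c in GAMMA3_EX1_TOP.items():
            assert g3.coefficient(k) == c

    def test_four_outcome_iterates(self, example2):
        trace = picard_iterates(example2, n=2)
        assert dict(trace.iterates[1].coeffs) == GAMMA1_EX2
        assert dict(trace.iterates[2].coeffs) == GAMMA2_EX2

    def test_degree_grows_by_two_per_step(self, example1_trace):
        for n, poly in enumerate(example1_trace.iterates):
            assert poly.degree == 1 + 2 * n

    def test_four_outcome_iterates_independent_of_p(self):
        traces = [
            picard_iterates(oq.preset_model("example2", {"p": p}), n=2)
            for p in (Fraction(0), Fraction(1, 4), Fraction(1, 2), Fraction(1))
        ]
        ref = traces[0]
        for tr in traces[1:]:
            for a, b in zip(ref.iterates, tr.iterates):
                assert dict(a.coeffs) == dict(b.coeffs)


class TestAgainstSymbolicOracle:
    @pytest.mark.parametrize("preset", ["example1", "example2", "berinde_khan"])
    def test_three_steps_match_independent_symbolic_integration(self, preset):
        model = oq.preset_model(preset, {})
        x, t = sp.symbols("x t")
        expr = x
        poly = RationalPolynomial.identity()
        for _ in range(3):
            expr = _sympy_picard_step(model, expr, x, t)
            poly = picard_step_exact(model, poly)
            assert sp.expand(_to_sympy(poly, x) - expr) == 0

    def test_affine_composition_matches_sympy_expansion(self):
        # the inner term of the second worked-example step
        poly = RationalPolynomial(GAMMA1_EX1)
        op = make_affine_operator(Fraction(1, 5), Fraction(2, 5))
        composed = poly_compose_affine(poly, op)
        t = sp.symbols("t")
        expected = sp.expand(_to_sympy(poly, t).subs(t, (t + 2) / 5))
        assert sp.expand(_to_sympy(composed, t) - expected) == 0


class TestPolynomialArithmetic:
    def test_identity_composed_with_affine(self):
        op = make_affine_operator(Fraction(1, 4), Fraction(1, 4))
        out = poly_compose_affine(RationalPolynomial.identity(), op)
        assert dict(out.coeffs) == {0: Fraction(1, 4), 1: Fraction(1, 4)}

    def test_composition_with_identity_map(self):
        op = make_affine_operator(1, 0)
        square = RationalPolynomial({2: Fraction(1)})
        assert dict(poly_compose_affine(square, op).coeffs) == {2: Fraction(1)}

    def test_evaluation_is_exact(self, example1_trace):
        g1 = example1_trace.iterates[1]
        assert evaluate_poly(g1, 1) == Fraction(53, 120)
        assert evaluate_poly(RationalPolynomial.identity(), 1) == 1

    def test_coefficient_query_lowest_terms(self, example1_trace):
        assert coefficient_query(example1_trace.iterates[2], 3) == (3217, 480000)
        assert coefficient_query(example1_trace.iterates[1], 1) == (2, 5)
        assert coefficient_query(RationalPolynomial.zero(), 5) == (0, 1)

    def test_zero_polynomial_is_fixed_by_step(self, example1):
        out = picard_step_exact(example1, RationalPolynomial.zero())
        assert out.degree == -1

    def test_iteration_cap_is_enforced(self, example1):
        with pytest.raises(ValueError, match="cap"):
            picard_iterates(example1, n=26)


small_polys = st.dictionaries(
    st.integers(min_value=0, max_value=4),
    st.fractions(min_value=-3, max_value=3, max_denominator=12),
    max_size=4,
).map(RationalPolynomial)
rationals = st.fractions(min_value=-5, max_value=5, max_denominator=10)


class TestOperatorProperties:
    @settings(max_examples=25, deadline=None)
    @given(p=small_polys, q=small_polys, a=rationals, b=rationals)
    def test_step_is_linear(self, example1, p, q, a, b):
        combo = p.scale(a) + q.scale(b)
        lhs = picard_step_exact(example1, combo)
        rhs = picard_step_exact(example1, p).scale(a) + picard_step_exact(example1, q).scale(b)
        assert dict(lhs.coeffs) == dict(rhs.coeffs)

    @settings(max_examples=25, deadline=None)
    @given(p=small_polys, q=small_polys)
    def test_step_is_nonexpansive_in_sup_norm(self, example1, p, q):
        """Weights sum to 1 and the range of integration is within [0, 1]."""
        before = (p - q).sup_norm(2001)
        tp, tq = picard_step_exact(example1, p), picard_step_exact(example1, q)
        after = (tp - tq).sup_norm(2001)
        assert after <= before + 1e-12

    @settings(max_examples=25, deadline=None)
    @given(p=small_polys)
    def test_every_image_vanishes_at_zero(self, example1, p):
        out = picard_step_exact(example1, p)
        assert evaluate_poly(out, 0) == 0

    def test_sup_norms_decay_monotonically(self, example1_trace):
        norms = [p.sup_norm() for p in example1_trace.iterates[1:]]
        assert norms[0] > norms[1] > norms[2]

    def test_trace_starts_at_gamma0_and_has_right_length(self, example1_trace):
        assert len(example1_trace) == 4
        assert dict(example1_trace.iterates[0].coeffs) == {1: Fraction(1)}
        assert len(example1_trace.sup_norm_deltas) == 3
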