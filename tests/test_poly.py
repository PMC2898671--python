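"""Polynomial core: evaluation, denominator clearing, interval enclosures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polycert import (Interval, Polynomial, RationalExpression,
                      clear_denominators, interval_bound, poly_evaluate)
from polycert.sets import InputSequence


def test_evaluate_monomial():
    p = Polynomial(("x1", "x2"), {(2, 1): 1.0})
    assert poly_evaluate(p, {"x1": 2.0, "x2": 3.0}) == 12.0


def test_evaluate_zero_polynomial():
    z = Polynomial.zero(("x", "y"))
    assert poly_evaluate(z, {}) == 0.0
    assert z.is_zero()


def test_evaluate_missing_variable_names_it():
    p = Polynomial(("x", "y"), {(1, 1): 2.0})
    with pytest.raises(KeyError, match="y"):
        poly_evaluate(p, {"x": 1.0})


def test_step_residual_vanishes_on_simulated_trajectory(mm):
    """Forward-simulation oracle: every simulated point is an exact root of
    the step polynomials."""
    system, cfg = mm
    p = {"p1": 0.8, "p2": 0.3, "p3": 0.5}
    traj = system.simulate({"S": 0.9, "C": 0.05}, p,
                           InputSequence.constant({}), 15)
    for k in range(15):
        assignment = dict(p)
        for st_name, val in traj.state_at(k).items():
            assignment[st_name] = val
        for st_name, val in traj.state_at(k + 1).items():
            assignment[st_name + "__next"] = val
        for g in system.step_polynomials(k):
            assert abs(poly_evaluate(g, assignment)) < 1e-12


def test_clear_denominators_michaelis_menten_flux():
    # p1*x/(p2+x) = rhs over a domain where p2 + x > 0
    variables = ("x", "rhs", "p1", "p2")
    x = Polynomial.variable(variables, "x")
    rhs = Polynomial.variable(variables, "rhs")
    p1 = Polynomial.variable(variables, "p1")
    p2 = Polynomial.variable(variables, "p2")
    expr = RationalExpression(rhs * (p2 + x) - p1 * x, p2 + x)
    domain = {"x": Interval(0, 1), "rhs": Interval(-5, 5),
              "p1": Interval(0, 1), "p2": Interval(0.5, 1)}
    cleared = clear_denominators(expr, domain)
    assert cleared.structurally_equal(rhs * p2 + rhs * x - p1 * x)


def test_clear_denominators_identity_for_polynomials():
    variables = ("x",)
    num = Polynomial(variables, {(2,): 3.0, (0,): -1.0})
    expr = RationalExpression.from_polynomial(num)
    out = clear_denominators(expr, {"x": Interval(-10, 10)})
    assert out.structurally_equal(num)


def test_clear_denominators_refuses_sign_change():
    variables = ("x",)
    x = Polynomial.variable(variables, "x")
    expr = RationalExpression(x, x - 0.5)
    with pytest.raises(ValueError, match="contains 0"):
        clear_denominators(expr, {"x": Interval(0, 1)})


@pytest.mark.parametrize("terms,box,expected", [
    ({(1, 1): 1.0}, {"a": (0, 1), "b": (2, 3)}, (0, 3)),
    ({(1, 0): 2.0, (0, 0): 1.0}, {"a": (0, 1), "b": (0, 1)}, (1, 3)),
])
def test_interval_bound_examples(terms, box, expected):
    p = Polynomial(("a", "b"), terms)
    iv = interval_bound(p, {k: Interval(*v) for k, v in box.items()})
    assert (iv.lower, iv.upper) == expected


def test_interval_bound_contains_exact_range():
    # x^2 - x on [0,1] has exact range [-0.25, 0]
    p = Polynomial(("x",), {(2,): 1.0, (1,): -1.0})
    iv = interval_bound(p, {"x": Interval(0, 1)})
    assert iv.lower <= -0.25 and iv.upper >= 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_enclosure_soundness_random(data):
    """Dense sampling of a random polynomial never escapes the enclosure."""
    n_vars = data.draw(st.integers(1, 3))
    variables = tuple(f"v{i}" for i in range(n_vars))
    n_terms = data.draw(st.integers(1, 5))
    terms = {}
    for _ in range(n_terms):
        exps = tuple(data.draw(st.integers(0, 3)) for _ in range(n_vars))
        coeff = data.draw(st.floats(-5, 5, allow_nan=False))
        terms[exps] = coeff
    p = Polynomial(variables, terms)
    box = {}
    for v in variables:
        lo = data.draw(st.floats(-2, 2, allow_nan=False))
        w = data.draw(st.floats(0, 2, allow_nan=False))
        box[v] = Interval(lo, lo + w)
    iv = p.interval_bound(box)
    rng = np.random.default_rng(0)
    pts = {v: rng.uniform(box[v].lower, box[v].upper, size=50)
           for v in variables}
    vals = [p.evaluate({v: pts[v][i] for v in variables})
            for i in range(50)]
    tol = 1e-9 * (1 + abs(iv.lower) + abs(iv.upper))
    assert min(vals) >= iv.lower - tol
    assert max(vals) <= iv.upper + tol


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_ring_axioms_random(data):
    variables = ("x", "y")
    def draw_poly():
        terms = {}
        for _ in range(data.draw(st.integers(1, 4))):
            exps = (data.draw(st.integers(0, 2)),
                    data.draw(st.integers(0, 2)))
            terms[exps] = data.draw(
                st.floats(-3, 3, allow_nan=False))
        return Polynomial(variables, terms)
    p, q, r = draw_poly(), draw_poly(), draw_poly()
    pt = {"x": data.draw(st.floats(-2, 2, allow_nan=False)),
          "y": data.draw(st.floats(-2, 2, allow_nan=False))}
    lhs = ((p + q) * r).evaluate(pt)
    rhs = (p * r).evaluate(pt) + (q * r).evaluate(pt)
    assert math.isclose(lhs, rhs, rel_tol=1e-9, abs_tol=1e-7)


def test_substitution_commutes_with_evaluation():
    variables = ("x", "y")
    p = Polynomial(variables, {(2, 0): 1.0, (1, 1): -2.0, (0, 0): 0.5})
    sub = Polynomial(variables, {(0, 1): 3.0, (0, 0): -1.0})  # x := 3y - 1
    composed = p.substitute({"x": sub})
    for yval in (-1.0, 0.3, 2.0):
        direct = p.evaluate({"x": 3 * yval - 1, "y": yval})
        assert math.isclose(composed.evaluate({"x": 0.0, "y": yval}),
                            direct, rel_tol=1e-12, abs_tol=1e-12)


def test_clear_denominators_zero_set_equivalence(rng):
    """On random domain points, the cleared polynomial has the same sign and
    zero status as the rational equation."""
    variables = ("x", "p")
    x = Polynomial.variable(variables, "x")
    p = Polynomial.variable(variables, "p")
    num = x * p - 0.3 * p + 0.1 * x
    den = p + 1.0
    expr = RationalExpression(num, den)
    domain = {"x": Interval(-1, 1), "p": Interval(0.5, 2)}
    cleared = clear_denominators(expr, domain)
    for _ in range(100):
        pt = {"x": rng.uniform(-1, 1), "p": rng.uniform(0.5, 2)}
        assert np.sign(cleared.evaluate(pt)) == np.sign(expr.evaluate(pt))
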