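"""Sparse multivariate polynomials, rational expressions and interval enclosures.

Everything downstream (difference systems, feasibility instances, the
quadratization and the SDP relaxation) is built on the :class:`Polynomial`
representation defined here: a map from integer exponent vectors to real
coefficients over a fixed, ordered tuple of variable names.  The variable
ordering is decided once per system and shared by every polynomial of that
system, so exponent vectors are directly comparable.

Interval bounds are computed per term (coefficient times a product of power
intervals).  The enclosure is sound but not tight; tightness is not needed
anywhere — bounds are used to box auxiliary lifted monomials and to check
sign-definiteness of denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

COEFF_DROP_TOL = 1e-14

Exponents = Tuple[int, ...]


@dataclass(frozen=True)
class Interval:
    """Closed real interval [lower, upper]."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.upper):
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, x: float, tol: float = 0.0) -> bool:
        return self.lower - tol <= x <= self.upper + tol

    def intersect(self, other: "Interval") -> "Interval | None":
        lo = max(self.lower, other.lower)
        hi = min(self.upper, other.upper)
        return Interval(lo, hi) if lo <= hi else None

    def __mul__(self, other: "Interval") -> "Interval":
        c = (self.lower * other.lower, self.lower * other.upper,
             self.upper * other.lower, self.upper * other.upper)
        return Interval(min(c), max(c))

    def __add__(self, other: "Interval") -> "Interval":
        return Interval(self.lower + other.lower, self.upper + other.upper)

    def scale(self, a: float) -> "Interval":
        if a >= 0:
            return Interval(a * self.lower, a * self.upper)
        return Interval(a * self.upper, a * self.lower)

    def power(self, n: int) -> "Interval":
        if n == 0:
            return Interval(1.0, 1.0)
        if n == 1:
            return self
        lo, hi = self.lower ** n, self.upper ** n
        if n % 2 == 1:
            return Interval(lo, hi)
        # even power: minimum at 0 if the interval straddles it
        if self.lower <= 0.0 <= self.upper:
            return Interval(0.0, max(lo, hi))
        return Interval(min(lo, hi), max(lo, hi))


class Polynomial:
    """Sparse multivariate polynomial over a fixed ordered variable tuple."""

    __slots__ = ("variables", "terms")

    def __init__(self, variables: Sequence[str],
                 terms: Mapping[Exponents, float] | None = None):
        self.variables: Tuple[str, ...] = tuple(variables)
        cleaned: Dict[Exponents, float] = {}
        if terms:
            n = len(self.variables)
            for exps, coeff in terms.items():
                if len(exps) != n:
                    raise ValueError(
                        f"exponent vector {exps} has length {len(exps)}, "
                        f"expected {n}")
                if abs(coeff) >= COEFF_DROP_TOL:
                    cleaned[tuple(int(e) for e in exps)] = float(coeff)
        self.terms: Dict[Exponents, float] = cleaned

    # -- constructors -------------------------------------------------

    @classmethod
    def zero(cls, variables: Sequence[str]) -> "Polynomial":
        return cls(variables, {})

    @classmethod
    def constant(cls, variables: Sequence[str], c: float) -> "Polynomial":
        return cls(variables, {(0,) * len(variables): c})

    @classmethod
    def variable(cls, variables: Sequence[str], name: str) -> "Polynomial":
        variables = tuple(variables)
        idx = variables.index(name)
        exps = tuple(1 if i == idx else 0 for i in range(len(variables)))
        return cls(variables, {exps: 1.0})

    # -- predicates ---------------------------------------------------

    def is_zero(self) -> bool:
        return not self.terms

    def degree(self) -> int:
        return max((sum(e) for e in self.terms), default=0)

    def used_variables(self) -> Tuple[str, ...]:
        used = [False] * len(self.variables)
        for exps in self.terms:
            for i, e in enumerate(exps):
                if e:
                    used[i] = True
        return tuple(v for v, u in zip(self.variables, used) if u)

    # -- arithmetic ---------------------------------------------------

    def _check(self, other: "Polynomial") -> None:
        if self.variables != other.variables:
            raise ValueError("polynomials over different variable orderings")

    def __add__(self, other: "Polynomial | float") -> "Polynomial":
        if not isinstance(other, Polynomial):
            other = Polynomial.constant(self.variables, float(other))
        self._check(other)
        terms = dict(self.terms)
        for exps, c in other.terms.items():
            terms[exps] = terms.get(exps, 0.0) + c
        return Polynomial(self.variables, terms)

    __radd__ = __add__

    def __neg__(self) -> "Polynomial":
        return Polynomial(self.variables,
                          {e: -c for e, c in self.terms.items()})

    def __sub__(self, other: "Polynomial | float") -> "Polynomial":
        if not isinstance(other, Polynomial):
            other = Polynomial.constant(self.variables, float(other))
        return self + (-other)

    def __rsub__(self, other: float) -> "Polynomial":
        return (-self) + other

    def __mul__(self, other: "Polynomial | float") -> "Polynomial":
        if not isinstance(other, Polynomial):
            return Polynomial(self.variables,
                              {e: c * float(other)
                               for e, c in self.terms.items()})
        self._check(other)
        terms: Dict[Exponents, float] = {}
        for e1, c1 in self.terms.items():
            for e2, c2 in other.terms.items():
                e = tuple(a + b for a, b in zip(e1, e2))
                terms[e] = terms.get(e, 0.0) + c1 * c2
        return Polynomial(self.variables, terms)

    __rmul__ = __mul__

    def __pow__(self, n: int) -> "Polynomial":
        if n < 0:
            raise ValueError("negative polynomial power")
        out = Polynomial.constant(self.variables, 1.0)
        for _ in range(n):
            out = out * self
        return out

    # -- evaluation & substitution ------------------------------------

    def evaluate(self, assignment: Mapping[str, float]) -> float:
        for v in self.used_variables():
            if v not in assignment:
                raise KeyError(f"assignment missing variable '{v}'")
        values = [assignment.get(v, 0.0) for v in self.variables]
        total = 0.0
        for exps, coeff in self.terms.items():
            prod = coeff
            for val, e in zip(values, exps):
                if e:
                    prod *= val ** e
            total += prod
        return total

    def substitute(self, mapping: Mapping[str, "Polynomial"]) -> "Polynomial":
        """Replace variables by polynomials (all over the same ordering)."""
        out = Polynomial.zero(self.variables)
        base = {v: Polynomial.variable(self.variables, v)
                for v in self.variables}
        base.update(mapping)
        for exps, coeff in self.terms.items():
            term = Polynomial.constant(self.variables, coeff)
            for v, e in zip(self.variables, exps):
                if e:
                    term = term * (base[v] ** e)
            out = out + term
        return out

    def rename_variables(self, new_variables: Sequence[str],
                         mapping: Mapping[str, str]) -> "Polynomial":
        """Re-express over a new ordering, renaming via `mapping`."""
        new_variables = tuple(new_variables)
        index = {v: i for i, v in enumerate(new_variables)}
        n = len(new_variables)
        terms: Dict[Exponents, float] = {}
        for exps, coeff in self.terms.items():
            new_exps = [0] * n
            for v, e in zip(self.variables, exps):
                if e:
                    target = mapping.get(v, v)
                    if target not in index:
                        raise KeyError(f"variable '{target}' not in new ordering")
                    new_exps[index[target]] += e
            key = tuple(new_exps)
            terms[key] = terms.get(key, 0.0) + coeff
        return Polynomial(new_variables, terms)

    # -- interval enclosure -------------------------------------------

    def interval_bound(self, box: Mapping[str, Interval]) -> Interval:
        """Sound enclosure of the range over a box (per-term arithmetic)."""
        for v in self.used_variables():
            if v not in box:
                raise KeyError(f"box missing variable '{v}'")
        total = Interval(0.0, 0.0)
        for exps, coeff in self.terms.items():
            term = Interval(1.0, 1.0)
            for v, e in zip(self.variables, exps):
                if e:
                    term = term * box[v].power(e)
            total = total + term.scale(coeff)
        return total

    # -- misc ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Polynomial):
            return NotImplemented
        return (self.variables == other.variables
                and self.terms == other.terms)

    def structurally_equal(self, other: "Polynomial",
                           tol: float = COEFF_DROP_TOL) -> bool:
        self._check(other)
        keys = set(self.terms) | set(other.terms)
        return all(
            math.isclose(self.terms.get(k, 0.0), other.terms.get(k, 0.0),
                         rel_tol=0.0, abs_tol=max(
                             tol, tol * abs(self.terms.get(k, 0.0))))
            for k in keys)

    def __repr__(self) -> str:
        if not self.terms:
            return "0"
        parts = []
        for exps, coeff in sorted(self.terms.items()):
            mono = "*".join(
                f"{v}^{e}" if e > 1 else v
                for v, e in zip(self.variables, exps) if e)
            parts.append(f"{coeff:g}*{mono}" if mono else f"{coeff:g}")
        return " + ".join(parts)


@dataclass
class RationalExpression:
    """Ratio of two polynomials over a common variable ordering."""

    numerator: Polynomial
    denominator: Polynomial

    def __post_init__(self) -> None:
        if self.denominator.is_zero():
            raise ValueError("zero denominator in rational expression")
        if self.numerator.variables != self.denominator.variables:
            raise ValueError("numerator/denominator variable orderings differ")

    @classmethod
    def from_polynomial(cls, p: Polynomial) -> "RationalExpression":
        return cls(p, Polynomial.constant(p.variables, 1.0))

    @property
    def variables(self) -> Tuple[str, ...]:
        return self.numerator.variables

    def is_polynomial(self) -> bool:
        d = self.denominator
        return list(d.terms.keys()) == [(0,) * len(d.variables)]

    def evaluate(self, assignment: Mapping[str, float]) -> float:
        den = self.denominator.evaluate(assignment)
        if den == 0.0:
            raise ZeroDivisionError("denominator vanishes at assignment")
        return self.numerator.evaluate(assignment) / den

    def __add__(self, other: "RationalExpression") -> "RationalExpression":
        return RationalExpression(
            self.numerator * other.denominator
            + other.numerator * self.denominator,
            self.denominator * other.denominator)

    def __neg__(self) -> "RationalExpression":
        return RationalExpression(-self.numerator, self.denominator)

    def __sub__(self, other: "RationalExpression") -> "RationalExpression":
        return self + (-other)

    def __mul__(self, other: "RationalExpression | Polynomial | float"
                ) -> "RationalExpression":
        if isinstance(other, RationalExpression):
            return RationalExpression(self.numerator * other.numerator,
                                      self.denominator * other.denominator)
        return RationalExpression(self.numerator * other, self.denominator)


def poly_evaluate(poly: Polynomial, assignment: Mapping[str, float]) -> float:
    """Evaluate Σ coeff·∏ v^exp at a point (module-level convenience)."""
    return poly.evaluate(assignment)


def interval_bound(poly: Polynomial, box: Mapping[str, Interval]) -> Interval:
    """Sound interval enclosure of `poly` over `box`."""
    return poly.interval_bound(box)


def clear_denominators(equation: RationalExpression,
                       domain: Mapping[str, Interval]) -> Polynomial:
    """Turn the rational equation ``equation == 0`` into a polynomial equation.

    The denominator must be provably sign-definite on `domain` (checked with
    the interval enclosure); otherwise multiplying through could change the
    zero set and the call refuses with a diagnostic.
    """
    if equation.is_polynomial():
        scale = equation.denominator.terms[
            (0,) * len(equation.denominator.variables)]
        return equation.numerator * (1.0 / scale)
    bound = equation.denominator.interval_bound(domain)
    if bound.lower <= 0.0 <= bound.upper:
        raise ValueError(
            "cannot clear denominator: interval enclosure "
            f"[{bound.lower:g}, {bound.upper:g}] of the denominator contains 0 "
            "on the given domain, so sign-definiteness cannot be guaranteed")
    return Polynomial(equation.numerator.variables,
                      dict(equation.numerator.terms))


def monomial_product(variables: Sequence[str],
                     exps: Iterable[int]) -> Polynomial:
    return Polynomial(tuple(variables), {tuple(exps): 1.0})
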