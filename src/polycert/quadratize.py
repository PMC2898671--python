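"""Monomial lifting: reduce a polynomial feasibility instance to degree <= 2.

Every monomial of degree above two is recursively factored into a product of
two registered variables.  Each distinct sub-monomial gets one auxiliary
variable w with a defining equality w - ξ_a·ξ_b = 0 and interval bounds
obtained by interval arithmetic over the original box; sub-monomials are
memoized so they are shared across all equations of the instance.

The projection of the lifted solution set onto the original variables equals
the original solution set: the defining equalities force every auxiliary to
its monomial value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

from .feasibility import FeasibilityInstance, LinearConstraint
from .poly import Interval, Polynomial

Exponents = Tuple[int, ...]


@dataclass
class QuadraticSystem:
    variables: Tuple[str, ...]           # original + auxiliary, in order
    bounds: Dict[str, Interval]
    equalities: List[Polynomial]         # degree <= 2 over `variables`
    inequalities: List[LinearConstraint]
    # auxiliary name -> (exponent vector over ORIGINAL variables,
    #                    factor pair of variable names)
    lifting: Dict[str, Tuple[Exponents, Tuple[str, str]]] = field(
        default_factory=dict)
    original_variables: Tuple[str, ...] = ()
    infeasible_by_construction: bool = False

    def lift_assignment(self, assignment: Mapping[str, float]
                        ) -> Dict[str, float]:
        """Extend a point on the original variables with auxiliary values."""
        out = {v: float(assignment[v]) for v in self.original_variables}
        for aux, (exps, _) in self.lifting.items():
            val = 1.0
            for v, e in zip(self.original_variables, exps):
                if e:
                    val *= out[v] ** e
            out[aux] = val
        return out


class _Lifter:
    def __init__(self, original: Tuple[str, ...],
                 bounds: Mapping[str, Interval]):
        self.original = original
        self.bounds = dict(bounds)
        self.memo: Dict[Exponents, str] = {}
        self.aux_order: List[str] = []
        self.lifting: Dict[str, Tuple[Exponents, Tuple[str, str]]] = {}

    def _monomial_interval(self, exps: Exponents) -> Interval:
        iv = Interval(1.0, 1.0)
        for v, e in zip(self.original, exps):
            if e:
                iv = iv * self.bounds[v].power(e)
        return iv

    def var_for(self, exps: Exponents) -> str:
        """Variable representing the monomial with exponent vector `exps`."""
        deg = sum(exps)
        if deg == 1:
            return self.original[exps.index(1)]
        if deg < 1:
            raise ValueError("cannot lift a constant monomial")
        if exps in self.memo:
            return self.memo[exps]
        left, right = self.split(exps)
        va = self.var_for(left)
        vb = self.var_for(right)
        name = "_w[" + "*".join(
            (f"{v}^{e}" if e > 1 else v)
            for v, e in zip(self.original, exps) if e) + "]"
        self.memo[exps] = name
        self.aux_order.append(name)
        self.lifting[name] = (exps, (va, vb))
        self.bounds[name] = self._monomial_interval(exps)
        return name

    @staticmethod
    def _flatten(exps: Exponents) -> List[int]:
        flat: List[int] = []
        for i, e in enumerate(exps):
            flat.extend([i] * e)
        return flat

    def split(self, exps: Exponents) -> Tuple[Exponents, Exponents]:
        """Balanced split of the flattened factor list, lower indexes first."""
        flat = self._flatten(exps)
        mid = (len(flat) + 1) // 2
        n = len(exps)
        left = [0] * n
        right = [0] * n
        for i in flat[:mid]:
            left[i] += 1
        for i in flat[mid:]:
            right[i] += 1
        return tuple(left), tuple(right)


def quadratize(instance: FeasibilityInstance) -> QuadraticSystem:
    """Lift the instance to an equivalent system of degree <= 2."""
    original = instance.variables
    for v in original:
        iv = instance.bounds[v]
        import math
        if not (math.isfinite(iv.lower) and math.isfinite(iv.upper)):
            raise ValueError(
                f"variable '{v}' is unbounded; monomial lifting requires "
                "finite bounds")
    lifter = _Lifter(original, instance.bounds)

    # pass 1: register auxiliaries for every high-degree monomial
    plans: List[List[Tuple[float, "Exponents | Tuple[str, str]"]]] = []
    for eq in instance.equalities:
        plan: List[Tuple[float, object]] = []
        for exps, coeff in eq.terms.items():
            if sum(exps) <= 2:
                plan.append((coeff, ("keep", exps)))
            else:
                left, right = lifter.split(exps)
                va = lifter.var_for(left)
                vb = lifter.var_for(right)
                plan.append((coeff, ("pair", (va, vb))))
        plans.append(plan)

    variables = original + tuple(lifter.aux_order)
    index = {v: i for i, v in enumerate(variables)}
    n = len(variables)

    def pair_exps(va: str, vb: str) -> Exponents:
        e = [0] * n
        e[index[va]] += 1
        e[index[vb]] += 1
        return tuple(e)

    equalities: List[Polynomial] = []
    for plan in plans:
        terms: Dict[Exponents, float] = {}
        for coeff, (kind, payload) in plan:
            if kind == "keep":
                key = tuple(payload) + (0,) * (n - len(original))
            else:
                key = pair_exps(*payload)
            terms[key] = terms.get(key, 0.0) + coeff
        equalities.append(Polynomial(variables, terms))

    # defining equalities w - ξ_a·ξ_b = 0
    for aux, (_, (va, vb)) in lifter.lifting.items():
        terms = {}
        e_aux = [0] * n
        e_aux[index[aux]] = 1
        terms[tuple(e_aux)] = 1.0
        key = pair_exps(va, vb)
        terms[key] = terms.get(key, 0.0) - 1.0
        equalities.append(Polynomial(variables, terms))

    return QuadraticSystem(
        variables=variables,
        bounds=dict(lifter.bounds),
        equalities=equalities,
        inequalities=list(instance.inequalities),
        lifting=dict(lifter.lifting),
        original_variables=original,
        infeasible_by_construction=instance.infeasible_by_construction)
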