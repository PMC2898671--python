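"""Assembly of the polynomial feasibility problem from model, data and priors.

The feasibility problem gathers, over a window of time indexes, the step
equalities of the difference system, the output equalities at measured
indexes, the set-membership constraints of measurements and uncertain
inputs, and the prior parameter/state boxes.  It is solvable iff the model
can reproduce the data for some parameter in the prior box — the object on
which infeasibility certificates operate.

Time-indexed variables are named ``state@k``; parameters keep their names.
Known (width-zero) inputs are substituted numerically; uncertain inputs
become bounded variables ``input@k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import DifferenceSystem, next_name
from .poly import Interval, Polynomial
from .sets import Box, InputSequence, MeasurementSequence, PolyhedralSet

TOL_EQ = 1e-8
TOL_INEQ = 1e-9


def timed(name: str, k: int) -> str:
    return f"{name}@{k}"


@dataclass
class LinearConstraint:
    """coeffs · z <= rhs over instance variables."""

    coeffs: Dict[str, float]
    rhs: float


@dataclass
class FeasibilityInstance:
    variables: Tuple[str, ...]
    bounds: Dict[str, Interval]
    equalities: List[Polynomial]
    inequalities: List[LinearConstraint]
    window: Tuple[int, int]
    provenance: Dict[str, object] = field(default_factory=dict)
    infeasible_by_construction: bool = False

    def __post_init__(self) -> None:
        for name in self.variables:
            if name not in self.bounds:
                raise ValueError(f"no bounds for variable '{name}'")


def _as_instance_poly(poly: Polynomial, inst_vars: Tuple[str, ...],
                      rename: Mapping[str, str],
                      constants: Mapping[str, float]) -> Polynomial:
    """Substitute known constants, then re-index onto instance variables."""
    if constants:
        mapping = {v: Polynomial.constant(poly.variables, c)
                   for v, c in constants.items()}
        poly = poly.substitute(mapping)
    return poly.rename_variables(inst_vars, dict(rename))


def build_feasibility_instance(
        system: DifferenceSystem,
        data: MeasurementSequence,
        inputs: InputSequence,
        param_box: Box,
        state_box: Box,
        window: Optional[Tuple[int, int]] = None,
        provenance: Optional[Dict[str, object]] = None,
        contract_bounds: bool = True,
) -> FeasibilityInstance:
    """Gather dynamics, outputs, measurements, inputs and priors over a window.

    The window defaults to [first measured index, last measured index]; it
    must span the data.  Every state of every index in the window is a
    variable bounded by the prior state box; the first state of the window
    is otherwise free (no initial condition is assumed).

    With `contract_bounds` (default) a forward interval-propagation sweep
    tightens the per-index state bounds: the interval image of the explicit
    step map applied to the bounds at index k soundly encloses every
    trajectory value at k+1, so intersecting it with the prior box never
    removes a feasible point but can shrink the boxes of unmeasured
    intermediate states dramatically (tighter lifting bounds and RLT cuts).
    """
    if window is None:
        window = data.window
    k0, k1 = window
    m_idx = data.indexes
    if m_idx and (m_idx[0] < k0 or m_idx[-1] > k1):
        raise ValueError("measurement index outside the window")
    for st in system.states:
        if st not in state_box:
            raise ValueError(f"state box missing state '{st}'")
    for p in system.parameters:
        if p not in param_box:
            raise ValueError(f"parameter box missing parameter '{p}'")

    names: List[str] = []
    bounds: Dict[str, Interval] = {}
    for k in range(k0, k1 + 1):
        for st in system.states:
            v = timed(st, k)
            names.append(v)
            bounds[v] = state_box[st]
    for p in system.parameters:
        names.append(p)
        bounds[p] = param_box[p]

    # uncertain inputs become variables; exact inputs are substituted
    input_var: Dict[Tuple[str, int], str] = {}
    input_const: Dict[int, Dict[str, float]] = {}
    for k in range(k0, k1 + 1):
        consts: Dict[str, float] = {}
        for u in system.inputs:
            iv = inputs.at(k).get(u)
            if iv is None:
                raise ValueError(f"no input set for '{u}' at index {k}")
            if iv.width == 0.0:
                consts[u] = iv.lower
            else:
                v = timed(u, k)
                input_var[(u, k)] = v
                names.append(v)
                bounds[v] = iv
        input_const[k] = consts

    inst_vars = tuple(names)
    equalities: List[Polynomial] = []
    inequalities: List[LinearConstraint] = []
    infeasible = False

    # pre-tighten state bounds from interval measurements of bare states
    for k in m_idx:
        mset = data.sets[k]
        if isinstance(mset, PolyhedralSet):
            continue
        for obs, iv in mset.items():
            expr = system.outputs.get(obs)
            if expr is None:
                raise ValueError(f"unknown observable '{obs}'")
            st = _bare_variable(expr)
            if st is None:
                continue
            var = timed(st, k)
            cap = bounds[var].intersect(iv)
            if cap is None:
                infeasible = True
            else:
                bounds[var] = cap

    if contract_bounds and not infeasible:
        infeasible = _forward_contract(system, bounds, inputs, input_const,
                                       window)

    # step equalities G_k for every consecutive index pair in the window
    for k in range(k0, k1):
        rename = {next_name(st): timed(st, k + 1) for st in system.states}
        rename.update({st: timed(st, k) for st in system.states})
        rename.update({u: input_var[(u, k)] for u in system.inputs
                       if (u, k) in input_var})
        for g in system.step_polynomials(k):
            equalities.append(_as_instance_poly(
                g, inst_vars, rename, input_const[k]))

    # measurement constraints at measured indexes
    obs_names = set(system.outputs)
    for k in m_idx:
        mset = data.sets[k]
        rename = {st: timed(st, k) for st in system.states}
        rename.update({u: input_var[(u, k)] for u in system.inputs
                       if (u, k) in input_var})
        if isinstance(mset, PolyhedralSet):
            exprs = {}
            for obs in mset.variables:
                if obs not in obs_names:
                    raise ValueError(f"unknown observable '{obs}'")
                exprs[obs] = _as_instance_poly(
                    system.outputs[obs], inst_vars, rename, input_const[k])
            for row, rhs in zip(mset.A, mset.b):
                combo = Polynomial.zero(inst_vars)
                for obs, a in zip(mset.variables, row):
                    if a:
                        combo = combo + exprs[obs] * float(a)
                lin = _linearize(combo, rhs)
                if lin is None:
                    raise ValueError(
                        "polyhedral measurement over a nonlinear output is "
                        "not supported")
                inequalities.append(lin)
            continue
        for obs, iv in mset.items():
            if obs not in obs_names:
                raise ValueError(f"unknown observable '{obs}'")
            expr = _as_instance_poly(
                system.outputs[obs], inst_vars, rename, input_const[k])
            var = _bare_variable(expr)
            if var is not None:
                cap = bounds[var].intersect(iv)
                if cap is None:
                    infeasible = True
                else:
                    bounds[var] = cap
                continue
            lo = _linearize((-expr), -iv.lower)
            hi = _linearize(expr, iv.upper)
            if lo is None or hi is None:
                # nonlinear output: add implicit output variable y@k
                yvar = timed("y_" + obs, k)
                inst_vars = inst_vars + (yvar,)
                names.append(yvar)
                bounds[yvar] = iv
                expr = expr.rename_variables(inst_vars, {})
                equalities = [e.rename_variables(inst_vars, {})
                              for e in equalities]
                equalities.append(
                    Polynomial.variable(inst_vars, yvar) - expr)
            else:
                inequalities.append(lo)
                inequalities.append(hi)

    if infeasible:
        # an empty bound intersection is itself a sound infeasibility
        # witness; encode it as the (trivially Farkas-certifiable) row
        # 0 <= -1 so the certificate machinery treats it uniformly
        inequalities.append(LinearConstraint({}, -1.0))
    inst = FeasibilityInstance(
        variables=tuple(names), bounds=bounds, equalities=equalities,
        inequalities=inequalities, window=window,
        provenance=dict(provenance or {}),
        infeasible_by_construction=infeasible)
    return inst


def _forward_contract(system: DifferenceSystem,
                      bounds: Dict[str, Interval],
                      inputs: InputSequence,
                      input_const: Dict[int, Dict[str, float]],
                      window: Tuple[int, int]) -> bool:
    """One forward interval-propagation sweep over the window.

    For an explicit step (each G affine in its own next-state variable with
    a constant coefficient and free of the others), the interval image of
    the step map over the index-k bounds soundly encloses every feasible
    value at k+1; the k+1 bounds are intersected with it.  Returns True if
    some intersection is empty (no trajectory fits — a sound proof of
    infeasibility).
    """
    from .model import NEXT_SUFFIX

    k0, k1 = window
    for k in range(k0, k1):
        box: Dict[str, Interval] = {}
        for st in system.states:
            box[st] = bounds[timed(st, k)]
        for p in system.parameters:
            box[p] = bounds[p]
        consts = input_const.get(k, {})
        for u in system.inputs:
            if u in consts:
                box[u] = Interval(consts[u], consts[u])
            else:
                box[u] = inputs.at(k)[u]
        for st, g in zip(system.states, system.step_polynomials(k)):
            nxt = next_name(st)
            idx = g.variables.index(nxt)
            coeff = None
            rest_terms = {}
            explicit = True
            for exps, c in g.terms.items():
                if exps[idx] == 0:
                    rest_terms[exps] = c
                    continue
                if exps[idx] > 1 or sum(exps) > exps[idx]:
                    explicit = False
                    break
                if any(e and g.variables[i].endswith(NEXT_SUFFIX)
                       for i, e in enumerate(exps) if i != idx):
                    explicit = False
                    break
                coeff = c
            if not explicit or coeff is None:
                continue
            rest = Polynomial(g.variables, rest_terms)
            try:
                img = rest.interval_bound(box).scale(-1.0 / coeff)
            except KeyError:
                continue
            var = timed(st, k + 1)
            cap = bounds[var].intersect(img)
            if cap is None:
                return True
            bounds[var] = cap
    return False


def _bare_variable(expr: Polynomial) -> Optional[str]:
    if len(expr.terms) != 1:
        return None
    (exps, coeff), = expr.terms.items()
    if coeff != 1.0 or sum(exps) != 1:
        return None
    return expr.variables[exps.index(1)]


def _linearize(expr: Polynomial, rhs: float) -> Optional[LinearConstraint]:
    """expr <= rhs as a linear constraint, or None if expr is nonlinear."""
    coeffs: Dict[str, float] = {}
    const = 0.0
    for exps, c in expr.terms.items():
        deg = sum(exps)
        if deg == 0:
            const += c
        elif deg == 1:
            coeffs[expr.variables[exps.index(1)]] = (
                coeffs.get(expr.variables[exps.index(1)], 0.0) + c)
        else:
            return None
    return LinearConstraint(coeffs, rhs - const)


def split_measurements(data: MeasurementSequence, window_length: int,
                       overlap: int) -> List[MeasurementSequence]:
    """Consecutive subsequences of `window_length` measurement indexes,
    adjacent ones sharing `overlap` indexes; their union covers the data."""
    idx = data.indexes
    m = len(idx)
    if window_length >= m:
        return [data]
    if not (1 <= overlap < window_length):
        raise ValueError("require 1 <= overlap < window_length")
    step = window_length - overlap
    out: List[MeasurementSequence] = []
    start = 0
    while True:
        end = start + window_length
        if end >= m:
            out.append(data.restrict(idx[m - window_length:]))
            break
        out.append(data.restrict(idx[start:end]))
        start += step
    return out


def split_runs(data: MeasurementSequence,
               gap_threshold: int = 50) -> List[MeasurementSequence]:
    """Split at large index gaps (disjoint experimental phases are treated
    as independent windows rather than one long coupled problem)."""
    idx = data.indexes
    runs: List[List[int]] = [[idx[0]]]
    for a, b in zip(idx, idx[1:]):
        if b - a > gap_threshold:
            runs.append([])
        runs[-1].append(b)
    return [data.restrict(r) for r in runs]


def residual_check(instance: FeasibilityInstance,
                   assignment: Mapping[str, float],
                   tol_eq: float = TOL_EQ,
                   tol_ineq: float = TOL_INEQ) -> Tuple[bool, float]:
    """Check a candidate point against all constraints of the instance.

    Returns (satisfied, max violation).  The maximum violation aggregates
    equality residuals, inequality slacks and bound violations.
    """
    max_eq = 0.0
    for eq in instance.equalities:
        max_eq = max(max_eq, abs(eq.evaluate(assignment)))
    max_in = 0.0
    for lin in instance.inequalities:
        val = sum(c * assignment[v] for v, c in lin.coeffs.items())
        max_in = max(max_in, val - lin.rhs)
    for v, iv in instance.bounds.items():
        if v in assignment:
            max_in = max(max_in, iv.lower - assignment[v],
                         assignment[v] - iv.upper)
    ok = (max_eq <= tol_eq and max_in <= tol_ineq
          and not instance.infeasible_by_construction)
    return ok, max(max_eq, max_in, 0.0)
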