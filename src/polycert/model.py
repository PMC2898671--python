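"""Reaction networks, mass-action ODEs and their Euler-discretized difference systems.

A :class:`ReactionNetwork` lists species and reactions in the general
reversible form  α·X  ⇌  β·X  with forward/reverse rate constants and an
optional rational prefactor (generalized mass action), plus optional
conservation substitutions that eliminate species whose concentration is an
affine function of the remaining states (moiety conservation).  From the
network we build the balance equations ẋ = N·ν and, by explicit fixed- or
variable-step Euler discretization, a system of polynomial implicit
difference equations G(x_{k+1}, x_k, p, u_k) = 0 together with polynomial
output equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .poly import (Interval, Polynomial, RationalExpression,
                   clear_denominators)
from .sets import Box, InputSequence

NEXT_SUFFIX = "__next"


def next_name(state: str) -> str:
    return state + NEXT_SUFFIX


@dataclass
class Reaction:
    """One (possibly reversible) reaction with integer stoichiometry.

    `prefactor` is an optional affine/rational factor F_j (generalized mass
    action); `input_multiplier` names an input signal multiplying the flux.
    """

    reactants: Dict[str, int]
    products: Dict[str, int]
    forward: str
    reverse: Optional[str] = None
    prefactor: Optional[RationalExpression] = None
    input_multiplier: Optional[str] = None
    name: str = ""


@dataclass
class ReactionNetwork:
    species: Tuple[str, ...]
    reactions: List[Reaction]
    parameters: Tuple[str, ...]
    inputs: Tuple[str, ...] = ()
    # eliminated species -> affine expression {state -> coeff} plus "1" -> const
    substitutions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    outputs: Optional[Dict[str, Dict[str, float]]] = None  # obs -> affine in states
    name: str = ""

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.parameters = tuple(self.parameters)
        self.inputs = tuple(self.inputs)
        for r in self.reactions:
            for sto in (r.reactants, r.products):
                for sp, coeff in sto.items():
                    if sp not in self.species:
                        raise ValueError(f"unknown species '{sp}' in reaction")
                    if int(coeff) != coeff or coeff < 0:
                        raise ValueError(
                            "stoichiometric coefficients must be "
                            f"non-negative integers, got {coeff}")
            for par in (r.forward, r.reverse):
                if par is not None and par not in self.parameters:
                    raise ValueError(f"rate parameter '{par}' not registered")
            if (r.input_multiplier is not None
                    and r.input_multiplier not in self.inputs):
                raise ValueError(
                    f"input '{r.input_multiplier}' not registered")
        for sp in self.substitutions:
            if sp not in self.species:
                raise ValueError(f"substituted species '{sp}' unknown")

    @property
    def states(self) -> Tuple[str, ...]:
        return tuple(s for s in self.species if s not in self.substitutions)


def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """N[i, j] = β_ij − α_ij over all species (one net column per reaction)."""
    N = np.zeros((len(network.species), len(network.reactions)), dtype=int)
    index = {sp: i for i, sp in enumerate(network.species)}
    for j, r in enumerate(network.reactions):
        for sp, a in r.reactants.items():
            N[index[sp], j] -= a
        for sp, b in r.products.items():
            N[index[sp], j] += b
    return N


@dataclass
class ODESystem:
    """ẋ = N·ν with rational right-hand sides, plus an explicit output map."""

    states: Tuple[str, ...]
    parameters: Tuple[str, ...]
    inputs: Tuple[str, ...]
    rhs: List[RationalExpression]
    # observable name -> polynomial expression over (states, parameters, inputs)
    outputs: Dict[str, Polynomial]
    name: str = ""

    @property
    def variables(self) -> Tuple[str, ...]:
        return self.states + self.parameters + self.inputs


def _affine_to_poly(variables: Tuple[str, ...],
                    affine: Mapping[str, float]) -> Polynomial:
    p = Polynomial.zero(variables)
    for key, coeff in affine.items():
        if key == "1":
            p = p + float(coeff)
        else:
            if key not in variables:
                raise ValueError(
                    f"substitution references unregistered symbol '{key}'")
            p = p + Polynomial.variable(variables, key) * float(coeff)
    return p


def ode_rhs(network: ReactionNetwork) -> ODESystem:
    """Build the balance equations ẋ = N·ν with generalized mass-action fluxes.

    Conservation substitutions are applied so that eliminated species appear
    only through their affine expressions in the remaining states.
    """
    states = network.states
    variables = states + network.parameters + network.inputs
    one = RationalExpression.from_polynomial(
        Polynomial.constant(variables, 1.0))

    subs_polys = {sp: _affine_to_poly(variables, aff)
                  for sp, aff in network.substitutions.items()}

    def species_poly(sp: str) -> Polynomial:
        if sp in subs_polys:
            return subs_polys[sp]
        return Polynomial.variable(variables, sp)

    fluxes: List[RationalExpression] = []
    for r in network.reactions:
        fwd = Polynomial.variable(variables, r.forward)
        for sp, a in r.reactants.items():
            fwd = fwd * (species_poly(sp) ** a)
        net = fwd
        if r.reverse is not None:
            rev = Polynomial.variable(variables, r.reverse)
            for sp, b in r.products.items():
                rev = rev * (species_poly(sp) ** b)
            net = net - rev
        flux = RationalExpression.from_polynomial(net)
        if r.prefactor is not None:
            pf = RationalExpression(
                r.prefactor.numerator.rename_variables(variables, {}),
                r.prefactor.denominator.rename_variables(variables, {}))
            flux = flux * pf
        if r.input_multiplier is not None:
            flux = flux * Polynomial.variable(variables, r.input_multiplier)
        fluxes.append(flux)

    N = stoichiometric_matrix(network)
    sp_index = {sp: i for i, sp in enumerate(network.species)}
    rhs: List[RationalExpression] = []
    for st in states:
        total = RationalExpression.from_polynomial(
            Polynomial.zero(variables))
        for j, flux in enumerate(fluxes):
            coeff = N[sp_index[st], j]
            if coeff:
                total = total + flux * float(coeff)
        rhs.append(total)

    if network.outputs is not None:
        outputs = {obs: _affine_to_poly(variables, aff)
                   for obs, aff in network.outputs.items()}
    else:
        outputs = {st: Polynomial.variable(variables, st) for st in states}
    return ODESystem(states, network.parameters, network.inputs, rhs,
                     outputs, name=network.name)


@dataclass
class DifferenceSystem:
    """Implicit polynomial step equations G and output equations H.

    Step polynomial i at index k is over the ordering
    (next states, states, parameters, inputs) and vanishes along any exact
    trajectory.  For a fixed step all G_k coincide; with a per-step list of
    step sizes they differ by index.
    """

    states: Tuple[str, ...]
    parameters: Tuple[str, ...]
    inputs: Tuple[str, ...]
    step_polys: List[List[Polynomial]]  # one list per distinct step
    step_sizes: List[float]             # h per step index (cycled if fixed)
    fixed_step: bool
    outputs: Dict[str, Polynomial]      # over (states, parameters, inputs)
    name: str = ""

    @property
    def step_variables(self) -> Tuple[str, ...]:
        return (tuple(next_name(s) for s in self.states) + self.states
                + self.parameters + self.inputs)

    def h_at(self, k: int) -> float:
        if self.fixed_step:
            return self.step_sizes[0]
        return self.step_sizes[k]

    def step_polynomials(self, k: int) -> List[Polynomial]:
        """The G polynomials advancing index k -> k+1."""
        if self.fixed_step:
            return self.step_polys[0]
        return self.step_polys[k]

    # -- explicit simulation ------------------------------------------

    def _explicit_next(self, k: int, xk: Mapping[str, float],
                       p: Mapping[str, float],
                       uk: Mapping[str, float]) -> Dict[str, float]:
        """Solve G(x_{k+1}, x_k, p, u_k) = 0 for x_{k+1}.

        Requires each G_i to be affine in its own next-state variable and
        free of the others (true for any explicit scheme).
        """
        assignment = dict(xk)
        assignment.update(p)
        assignment.update(uk)
        out: Dict[str, float] = {}
        for st, g in zip(self.states, self.step_polynomials(k)):
            nxt = next_name(st)
            idx = g.variables.index(nxt)
            coeff = 0.0
            rest = 0.0
            values = [assignment.get(v, 0.0) for v in g.variables]
            for exps, c in g.terms.items():
                e_next = exps[idx]
                if e_next > 1:
                    raise ValueError(
                        f"step polynomial for '{st}' is not affine in "
                        f"'{nxt}'; explicit simulation unavailable")
                prod = c
                for i, (val, e) in enumerate(zip(values, exps)):
                    if i == idx or not e:
                        continue
                    if g.variables[i].endswith(NEXT_SUFFIX):
                        raise ValueError(
                            f"step polynomial for '{st}' couples several "
                            "next-state variables; explicit simulation "
                            "unavailable")
                    prod *= val ** e
                if e_next == 1:
                    coeff += prod
                else:
                    rest += prod
            if coeff == 0.0:
                raise ValueError(
                    f"step polynomial for '{st}' does not involve '{nxt}'")
            out[st] = -rest / coeff
        return out

    def simulate(self, x0: Mapping[str, float], p: Mapping[str, float],
                 inputs: InputSequence, K: int,
                 start_index: int = 0) -> "Trajectory":
        """Forward-simulate K steps from x0 at `start_index` (explicit
        step form required)."""
        if K < 0:
            raise ValueError("K must be >= 0")
        states = {st: [float(x0[st])] for st in self.states}
        outs = {obs: [] for obs in self.outputs}
        applied: List[Dict[str, float]] = []
        current = {st: float(x0[st]) for st in self.states}
        for kk in range(K + 1):
            k = start_index + kk
            uk = inputs.value_at(k)
            assignment = dict(current)
            assignment.update(p)
            assignment.update(uk)
            for obs, expr in self.outputs.items():
                outs[obs].append(expr.evaluate(assignment))
            applied.append(uk)
            if kk == K:
                break
            nxt = self._explicit_next(k, current, p, uk)
            for st, val in nxt.items():
                if not np.isfinite(val):
                    raise ArithmeticError(
                        f"non-finite state '{st}' at index {k + 1}")
            current = nxt
            for st in self.states:
                states[st].append(current[st])
        return Trajectory(
            indexes=list(range(start_index, start_index + K + 1)),
            states={st: np.array(v) for st, v in states.items()},
            outputs={obs: np.array(v) for obs, v in outs.items()},
            inputs=applied)


@dataclass
class Trajectory:
    """Simulated state/output sequences at integer time indexes."""

    indexes: List[int]
    states: Dict[str, np.ndarray]
    outputs: Dict[str, np.ndarray]
    inputs: List[Dict[str, float]]

    def state_at(self, k: int) -> Dict[str, float]:
        i = self.indexes.index(k)
        return {st: float(v[i]) for st, v in self.states.items()}

    def output_at(self, k: int) -> Dict[str, float]:
        i = self.indexes.index(k)
        return {obs: float(v[i]) for obs, v in self.outputs.items()}


def discretize_euler(ode: ODESystem, h: "float | Sequence[float]",
                     state_box: Optional[Box] = None,
                     param_box: Optional[Box] = None) -> DifferenceSystem:
    """Explicit first-order Euler: G = x_{k+1} − x_k − h·f(x_k, p, u_k).

    Rational right-hand sides are cleared to polynomials; this requires the
    denominators to be sign-definite over the supplied state/parameter boxes.
    """
    hs = [float(h)] if np.isscalar(h) else [float(v) for v in h]
    if any(v <= 0 for v in hs):
        raise ValueError("time-step must be positive")
    fixed = np.isscalar(h)

    step_vars = (tuple(next_name(s) for s in ode.states) + ode.states
                 + ode.parameters + ode.inputs)
    domain: Dict[str, Interval] = {}
    if state_box is not None:
        domain.update(state_box.bounds)
    if param_box is not None:
        domain.update(param_box.bounds)

    def build(hk: float) -> List[Polynomial]:
        polys = []
        for st, f in zip(ode.states, ode.rhs):
            num = f.numerator.rename_variables(step_vars, {})
            den = f.denominator.rename_variables(step_vars, {})
            lhs = (Polynomial.variable(step_vars, next_name(st))
                   - Polynomial.variable(step_vars, st))
            # (x+ - x - h f) * den == den*(x+ - x) - h*num
            expr = RationalExpression(lhs * den - num * hk, den)
            polys.append(clear_denominators(expr, domain))
        return polys

    if fixed:
        step_polys = [build(hs[0])]
    else:
        step_polys = [build(hk) for hk in hs]

    out_vars = ode.states + ode.parameters + ode.inputs
    outputs = {obs: expr.rename_variables(out_vars, {})
               for obs, expr in ode.outputs.items()}
    return DifferenceSystem(
        states=ode.states, parameters=ode.parameters, inputs=ode.inputs,
        step_polys=step_polys, step_sizes=hs, fixed_step=fixed,
        outputs=outputs, name=ode.name)


def conserved_moieties(network: ReactionNetwork) -> np.ndarray:
    """Rational basis of the left nullspace of N (rows m with mᵀN = 0)."""
    N = stoichiometric_matrix(network)
    from scipy.linalg import null_space
    ns = null_space(N.T.astype(float))
    return ns.T
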