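# polycert

Set-membership parameter estimation and **conclusive model invalidation**
for polynomial/rational models of biochemical reaction networks.

## The problem

Kinetic experiments in systems biology rarely pin a model down: data are
sparse, measurement errors are large, and competing mechanisms (say, two
hypotheses for the same enzyme-catalyzed reaction) may both "fit" under a
least-squares criterion.  A local fit that fails to match the data proves
nothing — the optimizer may simply have missed the right parameters.

`polycert` takes the set-based view.  A measurement at time index *k* is an
interval (more generally a polyhedron) 𝒴ₖ guaranteed to contain the true
output; the question becomes whether the constraint system

    G(x_{k+1}, x_k, p, u_k) = 0        (discretized dynamics, k ∈ T)
    y_k ∈ 𝒴_k,  u_k ∈ 𝒰_k             (set-bounded data and inputs)
    p ∈ 𝒫,  x_k ∈ 𝒳                   (prior parameter / state boxes)

admits *any* solution.  Mass-action (and generalized mass-action) networks
make every G polynomial after Euler discretization, so this feasibility
problem is polynomial.  The package:

1. **lifts** it to degree ≤ 2 by monomial substitution (each auxiliary
   w = ξ_a ξ_b carries a defining equality and interval bounds),
2. **relaxes** it to a semidefinite program over a moment matrix
   Z ⪰ 0, Z₀₀ = 1, with bound-product (RLT) cuts, and
3. **certifies** infeasibility through a Farkas ray of the relaxation:
   multipliers (y_eq, y_in ≥ 0) with A_eqᵀy_eq + A_inᵀy_in ⪰ 0 and
   b_eqᵀy_eq + b_inᵀy_in < 0.  By weak duality an infeasible relaxation
   means an infeasible original problem — invalidation is *conclusive*,
   while a feasible-looking relaxation stays inconclusive (one-sided
   guarantee: no consistent parameterization is ever lost).

A bisection algorithm turns certificates into **guaranteed outer bounds**:
the parameter box is split recursively, certified-inconsistent boxes are
discarded, and boxes smaller than a relative precision ε are kept.  Long
measurement records are split into short overlapping windows whose
estimates are intersected.

The conic solve behind the certificates is an operator-splitting method on
the homogeneous self-dual embedding implemented in `polycert.conic`; every
candidate certificate is re-validated independently (eigenvalue margin
accounting in `polycert.certificates`), so solver inaccuracy can only cost
completeness, never soundness.

## Worked example

```python
from polycert import (Box, EstimationConfig, InputSequence, Reaction,
                      ReactionNetwork, discretize_euler, generate_measurements,
                      ode_rhs, outer_approximate, project_bounds)

net = ReactionNetwork(species=("A",),
                      reactions=[Reaction({"A": 1}, {}, "p")],
                      parameters=("p",))
system = discretize_euler(ode_rhs(net), 0.5)       # x' = x - 0.5 p x
inputs = InputSequence.constant({})

traj = system.simulate({"A": 1.0}, {"p": 0.42}, inputs, 6)
data = generate_measurements(traj, traj.indexes, sigma=0.05)  # ±5% intervals

approx = outer_approximate(system, data, inputs, Box({"p": (0.0, 1.0)}),
                           Box({"A": (0.0, 2.0)}), EstimationConfig(eps=0.05))
print(project_bounds(approx)["p"])
```

prints

```
Interval(lower=0.375, upper=0.46875)
```

— a certified enclosure of every decay rate consistent with the ±5%
interval data (the generating rate 0.42 is inside, as the soundness
guarantee demands; everything outside [0.375, 0.469] is *proven*
inconsistent).  `examples/` contains narrative scripts for mechanism
invalidation (Henri vs. Michaelis–Menten), single-parameter bounding, the
carnitine-shuttle measurement scenarios, and a hand-inspected certificate.

Shipped case models (`polycert.case_studies.build_case_model`): the
Michaelis–Menten and Henri enzyme mechanisms (two states after eliminating
the enzyme by E + C = 1) and a four-state carnitine-shuttle transport
model, each as a YAML config with priors and reference setups.

A thin CLI mirrors the library: `polycert simulate | make-data |
invalidate | estimate | scenarios | report`.

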