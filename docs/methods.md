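# Methods

## Model class and discretization

A reaction network is a list of (possibly reversible) reactions
α·X ⇌ β·X with non-negative integer stoichiometry, forward/reverse rate
constants, an optional rational prefactor F_j (generalized mass action,
covering saturation-type rate laws), and an optional input multiplier for
externally gated steps.  The balance equations ẋ = N·ν are assembled
symbolically; declared moiety conservations (e.g. total enzyme E + C
constant) substitute affine expressions for eliminated species, so reduced
systems stay polynomial/rational in the remaining states.

Dynamics are discretized by explicit first-order Euler,
G = x_{k+1} − x_k − h·f(x_k, p, u_k), at a fixed step h (a per-step list of
h values is supported and yields per-index step polynomials).  Rational
right-hand sides are multiplied through by their denominators; this is done
only when an interval enclosure proves the denominator sign-definite over
the prior boxes, so the zero set is unchanged.  Higher-order or adaptive
schemes are out of scope; the discretization error of the data-generating
trajectory is treated as absorbed in the measurement uncertainty, and no
claim is made about the continuous-time system when the step is too coarse
for the dynamics (stiff systems need care the package does not provide).

## Feasibility problem and bound contraction

For a window [k₀, k₁] the instance collects: one step equality per state
and consecutive index pair; interval measurement constraints at measured
indexes (a measurement of a bare state tightens that variable's bounds
directly; affine outputs become linear rows; other polynomial outputs get
an implicit output variable); box bounds 𝒫 on parameters and 𝒳 on every
per-index state.  Unmeasured observables impose nothing; the window's first
state is free inside 𝒳 (no initial condition is assumed), which is what
makes disjoint measurement phases independent windows.

Before relaxation, a forward interval-propagation sweep contracts the
per-index state bounds: for explicit steps, the interval image of the step
map over the index-k box soundly encloses every feasible value at k+1 and
is intersected with the prior box.  This never removes a feasible point but
shrinks the boxes of unmeasured intermediate states by orders of magnitude,
which both tightens the relaxation (lifting bounds and RLT cuts scale with
box widths) and conditions the conic solve.  An empty intersection is a
sound proof of infeasibility; it is encoded as the trivially certifiable
row 0 ≤ −1 so that the certificate machinery handles it uniformly.

## Quadratization and moment relaxation

Monomials of degree > 2 are recursively factored: the flattened factor
list, ordered by variable index, is split at its midpoint; each sub-monomial
of degree ≥ 2 becomes a memoized auxiliary variable with a defining
equality w − ξ_a ξ_b = 0 and interval-arithmetic bounds.  Sub-monomials are
shared across all equations of an instance.  The lifted system's solution
set projects exactly onto the original one.

Variables are affinely rescaled to [0, 1] (zero-width variables are
substituted out), and the rank-one matrix (1, ζ)(1, ζ)ᵀ is replaced by a
moment matrix Z ⪰ 0 with Z₀₀ = 1.  Each quadratic equality becomes one
linear functional on Z; bounds give 0 ≤ Z₀ᵢ ≤ 1; diagonal RLT rows
(ζᵢ(1−ζᵢ) ≥ 0 and (1−ζᵢ)² ≥ 0, linearized) are always present; the `pairs`
level adds the four bound products for every variable pair co-occurring in
a quadratic term, and `full` for all pairs.  `pairs` is the default: on the
case studies it certifies essentially everything `full` does at a fraction
of the rows.  This is a Shor-plus-RLT construction; the certified
invalidation thresholds depend on the relaxation strength, so a different
valid-cut family would shift them slightly.  Lasserre-type higher moment
levels are deliberately not implemented.

## Conic solve and validated certificates

The relaxation is solved as a cone feasibility problem (zero, nonneg and
PSD blocks) by operator splitting on the homogeneous self-dual embedding:
one sparse LU factorization of I + Q, then iterations of linear solve, cone
projection (nonneg clip and a PSD eigenprojection of the dual block) and
over-relaxation with α = 1.5.  Rows are ℓ₂-equilibrated.  The embedding
exposes primal infeasibility as a dual ray with bᵀy < 0.

Soundness never rests on the solver.  A candidate ray is accepted only by
the independent validator: clip y_in to ≥ 0, form S = A_eqᵀy_eq +
A_inᵀy_in and μ = b_eqᵀy_eq + b_inᵀy_in, and require

    μ + max(0, −λ_min(S))·(n+1) + (n+1)(1+‖S‖)·10⁻¹² ≤ −margin·max(1, |μ|)

with margin 10⁻⁷ and an absolute PSD tolerance of 10⁻⁸ on λ_min(S).  Since
every feasible Z has Z₀₀ = 1 and Zᵢᵢ ≤ 1 (bound and diagonal-RLT rows),
tr(Z) ≤ n+1, so the inequality quantitatively contradicts ⟨S, Z⟩ ≥
λ_min·tr(Z): a validated ray proves emptiness up to floating-point
eigenvalue error, which the explicit slack term dominates for these
problem sizes.  Anything else — solver failure, iteration cap, or a
feasible-looking relaxation — is UNDECIDED, the sound direction.  The
validator depends only on the multipliers and the relaxation data.

## Bisection and probing

The outer-approximation algorithm is a depth-first work queue (lower half
first, hence deterministic): discard a box on a validated certificate; keep
it when its relative size ‖Q‖ — the maximum per-dimension width ratio to
the initial box over the bisected dimensions — falls to ε; otherwise split
the largest relative dimension at its midpoint (ties to the lowest index).
Known parameters (e.g. the 3-PAR prior) are bounded but never bisected.
Budget exhaustion (depth or SDP-solve caps) keeps the box with a
diagnostic, again the sound direction: the kept union can only grow.

Before any SDP, a feasibility probe searches the box: forward simulations
from measurement-midpoint initial states at sampled parameters, then a
Nelder–Mead polish over (p, x₀) of the maximum relative violation.  A
verified feasible point proves the box undiscardable, so the certificate
call is skipped; probing never discards.  Default ε = 0.05.

Long records are split into overlapping sub-windows (default 3 measurement
indexes, overlap 1) after separating measurement phases at large index
gaps (> 50); per-window estimates are intersected.  Windowed estimation is
weaker than one coupled problem but makes the cost linear in the record
length.  `run_scenario` defaults to bounding-box mode — each free parameter
is bounded separately per window (bisecting only that coordinate) and the
intervals intersected — the polynomial-time variant; full-box bisection
(`mode="full"`) yields the joint boxes when the dimension permits.

## Synthetic data

The generator emulates interval measurements of simulated trajectories: at
each requested index and measured observable, [y(1−σ), y(1+σ)] with
relative half-width σ.  It reproduces set-bounded uncertainty exactly — by
construction the true trajectory lies inside every interval, which is what
the soundness guarantee ("the generating parameters are never lost")
assumes.  Real data differ in ways the generator does not emulate: outliers
that leave the interval (the guarantee is then vacuous for the affected
window), non-relative error structure, correlated errors, and model
mismatch between generator and candidate (exercised only in the
discrimination study, where data come from a different mechanism).  Passing
tests therefore show correctness of the machinery under honest interval
coverage, not robustness to misspecified intervals.

## Case studies

*Enzyme mechanism discrimination.*  Michaelis–Menten (E + S ⇌ C → E + P)
versus the Henri variant (dead-end complex, product through a direct
bimolecular step) — indistinguishable at steady state, distinguishable in
the transient.  Both reduce to two states (S, C) with total enzyme fixed
at 1, h = 0.1 s, 21 samples.  The Henri reference rates are (1.0, 1.0,
1.0): O(1) rates match the 2 s observation window, and the nullcline
q₁(1−c)s = q₂c then passes near (0.6, 0.4), the near-steady-state end of
the studied initial conditions.  The MM search box is [0, 2]³, wide enough
to contain the mimicking corner p₁ ≈ q₁ + q₃.  The invalidation scan walks
the σ grid (0.5% steps, 0.5–20%) upward: per σ, probe for a feasible
point, try whole-box certificates on short sub-windows (length 7) and the
full window, then bisect; the first σ that fails to invalidate stops the
scan (feasible sets grow with σ).

*Carnitine shuttle.*  Four states — cytosolic CoA~FA (x1), cytosolic free
carnitine (x2), mitochondrial CoA~FA (x3), mitochondrial free carnitine
(x4) — with supply p1·u (u the binary β-oxidation activity), reversible
cytosolic transferase (p2, p3) whose complex is eliminated by carnitine
conservation as C0 − x2, the antiporter p4·(C0 − x2)·x4, and the
mitochondrial transferase regenerating CoA~FA from the imported complex
pool at rate p5·(C0mi − x4).  p5 enters only x3's equation, so x3 must be
measured for p5 to be identifiable.  The released mitochondrial carnitine
is not recycled into the free pool within the model — the minimal closure
with that identifiability structure; x3 grows secularly at the equilibrium
flux, consistent with its role as the β-oxidation precursor pool.
Reference values: p* = (5.00e-4 μM s⁻¹, 1.03e-1, 2.36e-2, 1.85e-2,
2.50e-2 μM⁻¹s⁻¹/s⁻¹ as dimensionally appropriate), C0 = 0.33 μM,
C0mi = 1.00 μM, x0 = (0, C0, 0, C0mi), h = 5 s, u ≡ 1.  Scenario axes:
prior (3-PAR: p1, p5 within [0.95, 1.05] relative, not bisected; 5-PAR:
all free), density (DENSE k = 0..14 ∪ 300..314; SPARSE five points per
phase), error (1/2/4% relative), measured set (ALL, NOT-X3, NOT-X4,
NOT-X3-X4); unknown parameters start at relative bounds [0.5, 2].

## Problem sizes and numerical defaults

The shipped analyses run at desk scale: certificates use the `pairs` RLT
level with a 6000-iteration solver cap for discrimination scans and
1200–2000 for scenario estimation; bisection caps at 250 SDP solves per
scan point; scenario estimation uses windows of 3 measurements with
overlap 1 and ε between 0.1 and 0.5 depending on the check; the
comprehensive structural checks subsample (e.g. coarser σ grids for the
ordering property, single-parameter estimation for containment checks).
Equality tolerance for residual checks is 1e-8, inequality 1e-9;
polynomial coefficients below 1e-14 are dropped.  All randomness (probe
sampling, synthetic datasets) flows from explicit seeds; solver and
bisection are deterministic given the seed.

## Known limitations

Certificate power degrades near the feasibility boundary (the certified
invalidation threshold is a lower bound on the true one) and on windows
with long unmeasured gaps, where interval propagation of wide parameter
boxes leaves the relaxation loose — visible as SPARSE scenarios improving
bounds less than DENSE ones.  Validation is floating-point (no directed
rounding); the explicit error slack makes a false certificate require an
eigenvalue error far above anything observed at these dimensions, but the
guarantee is numerical, not exact-arithmetic.  States are never bisected
(a config hook exists but state estimation is not implemented), discrete
parameters and non-polyhedral measurement sets are unsupported, and the
exact solution of the unrelaxed polynomial feasibility problem is out of
scope.
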