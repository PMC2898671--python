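"""Anatomy of an infeasibility certificate on a three-line toy problem.

The constraint x^2 = 2 with x restricted to [0, 1] has no solution.  The
pipeline lifts the problem to a moment relaxation, the conic solver finds a
Farkas ray, and the validator recombines the ray into a PSD aggregate with
a strictly negative gap — a machine-checkable proof of emptiness that does
not depend on how the solver found the ray.
"""

import numpy as np

from polycert import (FeasibilityInstance, Interval, Polynomial,
                      build_shor_relaxation, check_infeasibility,
                      quadratize, validate_certificate)
from polycert.conic import svec_to_mat

equality = Polynomial(("x",), {(2,): 1.0, (0,): -2.0})   # x^2 - 2 = 0
instance = FeasibilityInstance(
    variables=("x",), bounds={"x": Interval(0.0, 1.0)},
    equalities=[equality], inequalities=[], window=(0, 0))

relaxation = build_shor_relaxation(quadratize(instance), rlt_level="diag")
result = check_infeasibility(relaxation)

print(f"status: {result.status} after {result.iterations} iterations")
print(f"certified gap (mu < 0): {-result.margin:.6f}")
meq = relaxation.A_eq.shape[0]
y_eq, y_in = result.multipliers[:meq], np.maximum(
    result.multipliers[meq:], 0.0)
S = svec_to_mat(relaxation.A_eq.T @ y_eq + relaxation.A_in.T @ y_in,
                relaxation.dim)
print(f"aggregate S eigenvalues: {np.round(np.linalg.eigvalsh(S), 6)}")
print(f"independent validation: {validate_certificate(result.multipliers, relaxation)}")
# S is PSD and the multiplier combination of the constraint values is
# negative: no moment matrix can satisfy all rows, so no x in [0, 1] with
# x^2 = 2 exists.
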