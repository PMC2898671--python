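"""Validated infeasibility certificates for moment relaxations.

A Farkas ray for the relaxation is a pair of multiplier vectors (y_eq free,
y_in >= 0) over the linear functionals such that

    S := A_eqᵀ y_eq + A_inᵀ y_in  is positive semidefinite (as a matrix) and
    μ := b_eqᵀ y_eq + b_inᵀ y_in < 0 .

For any moment matrix Z feasible for the relaxation, ⟨S, Z⟩ <= μ < 0 while
⟨S, Z⟩ >= 0 — a contradiction, so the relaxation (hence the original
polynomial feasibility problem, by weak duality of the lifting) admits no
solution.  Validation is quantitative: since every feasible Z satisfies
Z[0,0] = 1 and Z[i,i] <= 1 (bound + diagonal RLT rows), tr(Z) <= dim, so a
slightly indefinite S with λ_min(S) = -δ still certifies provided
μ + δ·dim < 0 with margin.  Validation depends only on the multipliers and
the relaxation data, never on solver internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp

from .conic import ConeProblem, ConeSolution, solve_feasibility, svec_to_mat
from .feasibility import FeasibilityInstance
from .quadratize import quadratize
from .relaxation import SDPRelaxation, build_shor_relaxation

INFEASIBLE_CERTIFIED = "INFEASIBLE_CERTIFIED"
UNDECIDED = "UNDECIDED"

DEFAULT_MARGIN = 1e-7
DEFAULT_TOL_PSD = 1e-8


@dataclass
class CertificateResult:
    status: str
    multipliers: Optional[np.ndarray] = None   # over (eq rows, ineq rows)
    margin: float = 0.0
    solver_status: str = ""
    iterations: int = 0
    diagnostics: Dict[str, float] = field(default_factory=dict)

    @property
    def certified(self) -> bool:
        return self.status == INFEASIBLE_CERTIFIED


def validate_certificate(multipliers: np.ndarray,
                         relaxation: SDPRelaxation,
                         margin: float = DEFAULT_MARGIN,
                         tol_psd: float = DEFAULT_TOL_PSD) -> bool:
    """Independently check a Farkas ray against the relaxation data.

    Inequality multipliers are clipped to be non-negative before the check,
    so a ray with slightly negative entries is validated on its clipped
    version (which is itself a legitimate candidate).
    """
    meq = relaxation.A_eq.shape[0]
    m_in = relaxation.A_in.shape[0]
    if multipliers is None or multipliers.shape[0] != meq + m_in:
        return False
    y_eq = np.asarray(multipliers[:meq], dtype=float)
    y_in = np.maximum(np.asarray(multipliers[meq:], dtype=float), 0.0)
    if not (np.all(np.isfinite(y_eq)) and np.all(np.isfinite(y_in))):
        return False
    S_svec = relaxation.A_eq.T @ y_eq + relaxation.A_in.T @ y_in
    mu = float(relaxation.b_eq @ y_eq + relaxation.b_in @ y_in)
    S = svec_to_mat(S_svec, relaxation.dim)
    fro = float(np.linalg.norm(S))
    lam_min = float(np.linalg.eigvalsh(S)[0]) if fro > 0 else 0.0
    if lam_min < -tol_psd * (1.0 + fro):
        return False
    eig_err = relaxation.dim * (1.0 + fro) * 1e-12
    slack = mu + max(0.0, -lam_min) * relaxation.dim + eig_err
    scale = max(1.0, abs(mu))
    return slack <= -margin * scale


def _assemble_cone_problem(relaxation: SDPRelaxation
                           ) -> tuple[ConeProblem, np.ndarray]:
    """Stack the relaxation into standard conic form with row equilibration.

    Returns the problem and the row scaling factors (ordered eq rows then
    ineq rows) needed to map solver multipliers back to the unscaled rows.
    """
    A_eq, b_eq = relaxation.A_eq, relaxation.b_eq
    A_in, b_in = relaxation.A_in, relaxation.b_in

    def row_norms(A: sp.csr_matrix) -> np.ndarray:
        sq = np.asarray(A.multiply(A).sum(axis=1)).ravel()
        n = np.sqrt(sq)
        n[n == 0.0] = 1.0
        return n

    ne = row_norms(A_eq)
    ni = row_norms(A_in)
    De = sp.diags(1.0 / ne)
    Di = sp.diags(1.0 / ni)
    A = sp.vstack([De @ A_eq, Di @ A_in,
                   -sp.eye(relaxation.svec_dim, format="csr")],
                  format="csr")
    b = np.concatenate([b_eq / ne, b_in / ni,
                        np.zeros(relaxation.svec_dim)])
    problem = ConeProblem(A=A, b=b, m_eq=A_eq.shape[0],
                          m_in=A_in.shape[0], psd_dim=relaxation.dim)
    return problem, np.concatenate([ne, ni])


def check_infeasibility(relaxation: SDPRelaxation,
                        max_iters: int = 20000,
                        check_every: int = 100,
                        feas_tol: float = 1e-6,
                        margin: float = DEFAULT_MARGIN,
                        tol_psd: float = DEFAULT_TOL_PSD
                        ) -> CertificateResult:
    """Attempt to certify that the relaxation has no feasible moment matrix.

    Returns INFEASIBLE_CERTIFIED only with a validated Farkas ray; numerical
    failure, iteration exhaustion or a feasible relaxation all yield
    UNDECIDED (the sound direction — no instance with a feasible lifted
    point can ever be certified, by weak duality).
    """
    problem, scales = _assemble_cone_problem(relaxation)

    def validator(scaled_ray: np.ndarray) -> bool:
        return validate_certificate(scaled_ray / scales, relaxation,
                                    margin=margin, tol_psd=tol_psd)

    try:
        sol: ConeSolution = solve_feasibility(
            problem, validator, max_iters=max_iters,
            check_every=check_every, feas_tol=feas_tol)
    except (np.linalg.LinAlgError, RuntimeError) as exc:
        return CertificateResult(status=UNDECIDED,
                                 solver_status=f"solver failure: {exc}")

    if sol.status == "infeasibility_ray":
        ray = sol.y / scales
        return CertificateResult(
            status=INFEASIBLE_CERTIFIED, multipliers=ray,
            margin=float(-(relaxation.b_eq @ ray[:relaxation.A_eq.shape[0]]
                           + relaxation.b_in
                           @ np.maximum(ray[relaxation.A_eq.shape[0]:], 0.0))),
            solver_status=sol.status, iterations=sol.iterations,
            diagnostics=dict(sol.diagnostics))
    return CertificateResult(status=UNDECIDED, solver_status=sol.status,
                             iterations=sol.iterations,
                             diagnostics=dict(sol.diagnostics))


def certify_instance(instance: FeasibilityInstance,
                     rlt_level: str = "pairs",
                     **solver_kwargs) -> CertificateResult:
    """Pipeline convenience: quadratize, relax, attempt certification."""
    quadsys = quadratize(instance)
    relaxation = build_shor_relaxation(quadsys, rlt_level=rlt_level)
    return check_infeasibility(relaxation, **solver_kwargs)
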