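"""First-order conic solver for zero/nonneg/PSD cone feasibility problems.

Solves problems of the form

    find  x  such that  A x + w = b,   w ∈ K,
    K = {0}^m_eq × R₊^m_in × S₊  (PSD block in svec coordinates)

via operator splitting on the homogeneous self-dual embedding (the SCS
iteration: a single sparse factorization of I + Q, then alternating linear
solves and cone projections).  The embedding makes infeasibility detection
natural: a primal-infeasibility (Farkas) ray appears in the dual iterate y
with bᵀy < 0, Aᵀy = 0, y ∈ K*.

The solver itself is heuristic in finite time; every candidate certificate
is handed to a caller-supplied validator and only a validated ray is ever
reported, so downstream soundness never depends on solver accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

_SQ2 = math.sqrt(2.0)


def _svec_indices(dim: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row/column indices of the svec ordering (column-major upper
    triangle) and the positions of the diagonal entries within it."""
    rows, cols, diag = [], [], []
    idx = 0
    for j in range(dim):
        for i in range(j + 1):
            rows.append(i)
            cols.append(j)
            if i == j:
                diag.append(idx)
            idx += 1
    return np.array(rows), np.array(cols), np.array(diag)


_svec_cache: Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _svec_idx(dim: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    if dim not in _svec_cache:
        _svec_cache[dim] = _svec_indices(dim)
    return _svec_cache[dim]


def svec_to_mat(v: np.ndarray, dim: int) -> np.ndarray:
    rows, cols, diag = _svec_idx(dim)
    M = np.zeros((dim, dim))
    scaled = v / _SQ2
    M[rows, cols] = scaled
    d = np.arange(dim)
    M[d, d] = v[diag]
    M = M + M.T
    M[d, d] *= 0.5
    return M


def mat_to_svec(M: np.ndarray) -> np.ndarray:
    dim = M.shape[0]
    rows, cols, diag = _svec_idx(dim)
    v = M[rows, cols] * _SQ2
    v[diag] = np.diag(M)
    return v


def _psd_project_svec(v: np.ndarray, dim: int) -> np.ndarray:
    M = svec_to_mat(v, dim)
    w, V = np.linalg.eigh(M)
    if w[0] >= 0.0:
        return v
    pos = w > 0.0
    if not np.any(pos):
        return np.zeros_like(v)
    P = (V[:, pos] * w[pos]) @ V[:, pos].T
    return mat_to_svec(P)


@dataclass
class ConeProblem:
    A: sp.csr_matrix          # stacked (eq rows, ineq rows, -I psd block)
    b: np.ndarray
    m_eq: int
    m_in: int
    psd_dim: int              # matrix dimension of the PSD block

    @property
    def m_psd(self) -> int:
        return self.psd_dim * (self.psd_dim + 1) // 2


@dataclass
class ConeSolution:
    status: str               # "infeasibility_ray" | "feasible" | "inconclusive"
    iterations: int
    y: Optional[np.ndarray] = None        # dual ray over eq+ineq rows
    x: Optional[np.ndarray] = None        # primal point (svec coordinates)
    diagnostics: Dict[str, float] = field(default_factory=dict)


def solve_feasibility(
        problem: ConeProblem,
        certificate_validator: Callable[[np.ndarray], bool],
        max_iters: int = 20000,
        check_every: int = 100,
        feas_tol: float = 1e-6,
        alpha: float = 1.5,
) -> ConeSolution:
    """Run the homogeneous self-dual ADMM until a validated infeasibility
    ray, an (approximately) feasible primal point, or the iteration cap.

    `certificate_validator` receives the dual iterate restricted to the
    equality/inequality rows (normalized so that −bᵀy = 1) and must return
    True only for rays it can independently validate; the solver stops on
    the first validated ray.
    """
    A = problem.A.tocsr()
    b = problem.b
    m, nx = A.shape
    meq, min_, mpsd = problem.m_eq, problem.m_in, problem.m_psd
    dim = problem.psd_dim
    if m != meq + min_ + mpsd:
        raise ValueError("cone dimensions inconsistent with A")

    N = nx + m + 1
    # Q = [[0, A^T, 0], [-A, 0, b], [0, -b^T, 0]]   (objective c = 0)
    Q = sp.bmat([
        [None, A.T, None],
        [-A, None, b.reshape(-1, 1)],
        [None, -b.reshape(1, -1), None],
    ], format="csc")
    M = (sp.eye(N, format="csc") + Q).tocsc()
    lu = spla.splu(M)

    u = np.zeros(N)
    v = np.zeros(N)
    u[-1] = 1.0
    v[-1] = 1.0

    sl_x = slice(0, nx)
    sl_y = slice(nx, nx + m)
    sl_yin = slice(nx + meq, nx + meq + min_)
    sl_ypsd = slice(nx + meq + min_, nx + m)

    bnorm = np.linalg.norm(b) + 1.0

    for it in range(1, max_iters + 1):
        ut = lu.solve(u + v)
        if alpha != 1.0:
            ut = alpha * ut + (1.0 - alpha) * u
        r = ut - v
        # project onto C = R^nx × K* × R+
        if min_:
            r[sl_yin] = np.maximum(r[sl_yin], 0.0)
        r[sl_ypsd] = _psd_project_svec(r[sl_ypsd], dim)
        r[-1] = max(r[-1], 0.0)
        v = v - ut + r
        u = r

        if it % check_every == 0 or it == max_iters:
            y = u[sl_y]
            ip = float(b @ y)
            if ip < -1e-12 * bnorm:
                ray = y[:meq + min_] / (-ip)
                if certificate_validator(ray):
                    return ConeSolution(
                        status="infeasibility_ray", iterations=it,
                        y=ray, diagnostics={"b_dot_y": ip})
            tau = u[-1]
            if tau > 1e-9:
                x = u[sl_x] / tau
                w = b - A @ x
                res_eq = (float(np.max(np.abs(w[:meq]))) if meq else 0.0)
                res_in = (max(0.0, float(np.max(-w[meq:meq + min_])))
                          if min_ else 0.0)
                lam = float(np.linalg.eigvalsh(svec_to_mat(x, dim))[0])
                scale = 1.0 + float(np.max(np.abs(x)))
                if (res_eq <= feas_tol * scale
                        and res_in <= feas_tol * scale
                        and lam >= -feas_tol * scale):
                    return ConeSolution(
                        status="feasible", iterations=it, x=x,
                        diagnostics={"res_eq": res_eq, "res_in": res_in,
                                     "min_eig": lam})
    return ConeSolution(status="inconclusive", iterations=max_iters)
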