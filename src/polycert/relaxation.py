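"""Shor moment relaxation with reformulation-linearization (RLT) cuts.

The quadratic system is first affinely rescaled so every free variable lives
in [0, 1] (zero-width variables are substituted out as constants), then the
rank-one outer product (1, ζ)(1, ζ)ᵀ is replaced by a positive semidefinite
moment matrix Z with Z[0,0] = 1.  Every quadratic equality becomes one
linear functional on Z; variable bounds, and products of bound constraints
(RLT) at a chosen strength level, become linear inequality functionals.

Symmetric matrices are handled in scaled-vector (svec) form so that
⟨Q, Z⟩ = svec(Q)·svec(Z); the relaxation is stored as two sparse systems
A_eq·svec(Z) = b_eq and A_in·svec(Z) <= b_in over the svec coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import scipy.sparse as sp

from .poly import Polynomial
from .quadratize import QuadraticSystem

RLT_LEVELS = ("diag", "pairs", "full")


@dataclass
class SDPRelaxation:
    variables: Tuple[str, ...]      # free (scaled) variables, ζ_i ∈ [0,1]
    lows: np.ndarray                # ξ = low + width·ζ
    widths: np.ndarray
    fixed: Dict[str, float]
    n: int                          # number of free variables
    dim: int                        # moment matrix dimension n+1
    svec_dim: int
    A_eq: sp.csr_matrix
    b_eq: np.ndarray
    A_in: sp.csr_matrix
    b_in: np.ndarray
    rlt_level: str
    rlt_pairs: List[Tuple[int, int]] = field(default_factory=list)
    infeasible_by_construction: bool = False

    # -- svec helpers --------------------------------------------------

    def svec_index(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        # column-major upper triangle: entries with max index j come first
        return j * (j + 1) // 2 + i

    def mat_from_svec(self, v: np.ndarray) -> np.ndarray:
        d = self.dim
        M = np.zeros((d, d))
        isq = 1.0 / math.sqrt(2.0)
        idx = 0
        for j in range(d):
            for i in range(j + 1):
                if i == j:
                    M[i, i] = v[idx]
                else:
                    M[i, j] = M[j, i] = v[idx] * isq
                idx += 1
        return M

    def svec_from_mat(self, M: np.ndarray) -> np.ndarray:
        d = self.dim
        v = np.zeros(self.svec_dim)
        sq = math.sqrt(2.0)
        idx = 0
        for j in range(d):
            for i in range(j + 1):
                v[idx] = M[i, i] if i == j else M[i, j] * sq
                idx += 1
        return v

    def point_to_moment_svec(self, assignment: Dict[str, float]
                             ) -> np.ndarray:
        """svec of the rank-one moment matrix of a (scaled) feasible point."""
        z = np.empty(self.n + 1)
        z[0] = 1.0
        for i, v in enumerate(self.variables):
            w = self.widths[i]
            z[i + 1] = (assignment[v] - self.lows[i]) / w
        return self.svec_from_mat(np.outer(z, z))


class _RowBuilder:
    def __init__(self, relax_dim: int, svec_dim: int,
                 index_fn) -> None:
        self.svec_dim = svec_dim
        self.index = index_fn
        self.rows: List[Dict[int, float]] = []
        self.rhs: List[float] = []

    def add(self, entries: Dict[Tuple[int, int], float], rhs: float) -> None:
        """entries maps (i,j) of the SYMMETRIC matrix Q to Q_ij (i<=j);
        the functional is ⟨Q, Z⟩ counting off-diagonals twice."""
        row: Dict[int, float] = {}
        sq = math.sqrt(2.0)
        for (i, j), q in entries.items():
            k = self.index(i, j)
            row[k] = row.get(k, 0.0) + (q if i == j else q * sq)
        self.rows.append(row)
        self.rhs.append(rhs)

    def to_sparse(self) -> Tuple[sp.csr_matrix, np.ndarray]:
        data, ri, ci = [], [], []
        for r, row in enumerate(self.rows):
            for c, v in row.items():
                ri.append(r)
                ci.append(c)
                data.append(v)
        A = sp.csr_matrix((data, (ri, ci)),
                          shape=(len(self.rows), self.svec_dim))
        return A, np.array(self.rhs)


def _scaled_quadratic_entries(
        poly: Polynomial, var_index: Dict[str, int],
        lows: Dict[str, float], widths: Dict[str, float],
        fixed: Dict[str, float]) -> Tuple[Dict[Tuple[int, int], float], float]:
    """Entries of the symmetric matrix Q (over indices 1..n, with 0 the
    homogenizing coordinate) for the polynomial in scaled coordinates.
    Off-diagonal convention: Q_ij such that ⟨Q,Z⟩ counts Q_ij twice."""
    entries: Dict[Tuple[int, int], float] = {}

    def bump(i: int, j: int, val: float) -> None:
        key = (i, j) if i <= j else (j, i)
        entries[key] = entries.get(key, 0.0) + val

    for exps, coeff in poly.terms.items():
        factors = []
        for v, e in zip(poly.variables, exps):
            factors.extend([v] * e)
        if len(factors) == 0:
            bump(0, 0, coeff)
        elif len(factors) == 1:
            v = factors[0]
            if v in fixed:
                bump(0, 0, coeff * fixed[v])
            else:
                i = var_index[v] + 1
                bump(0, 0, coeff * lows[v])
                bump(0, i, coeff * widths[v] / 2.0)
        elif len(factors) == 2:
            va, vb = factors
            # (la + wa ζa)(lb + wb ζb)
            if va in fixed and vb in fixed:
                bump(0, 0, coeff * fixed[va] * fixed[vb])
            elif va in fixed or vb in fixed:
                if vb in fixed:
                    va, vb = vb, va
                # va fixed
                cval = coeff * fixed[va]
                j = var_index[vb] + 1
                bump(0, 0, cval * lows[vb])
                bump(0, j, cval * widths[vb] / 2.0)
            else:
                i = var_index[va] + 1
                j = var_index[vb] + 1
                bump(0, 0, coeff * lows[va] * lows[vb])
                bump(0, j, coeff * lows[va] * widths[vb] / 2.0)
                bump(0, i, coeff * lows[vb] * widths[va] / 2.0)
                w2 = coeff * widths[va] * widths[vb]
                if i == j:
                    bump(i, i, w2)
                else:
                    bump(i, j, w2 / 2.0)
        else:  # degree > 2 cannot appear after quadratization
            raise ValueError("polynomial of degree > 2 in quadratic system")
    const = entries.pop((0, 0), 0.0)
    return entries, const


def build_shor_relaxation(quadsys: QuadraticSystem,
                          rlt_level: str = "pairs") -> SDPRelaxation:
    """Build the moment relaxation of a quadratic system.

    rlt_level:
      * ``diag``  — bound products (ζ_i, 1−ζ_i) with themselves only;
      * ``pairs`` — additionally all variable pairs co-occurring in a
        quadratic term of some equality;
      * ``full``  — all variable pairs.
    """
    if rlt_level not in RLT_LEVELS:
        raise ValueError(f"unknown rlt level '{rlt_level}'")

    fixed: Dict[str, float] = {}
    free: List[str] = []
    for v in quadsys.variables:
        iv = quadsys.bounds[v]
        if iv.width == 0.0:
            fixed[v] = iv.lower
        else:
            free.append(v)
    var_index = {v: i for i, v in enumerate(free)}
    n = len(free)
    dim = n + 1
    svec_dim = dim * (dim + 1) // 2
    lows = {v: quadsys.bounds[v].lower for v in free}
    widths = {v: quadsys.bounds[v].width for v in free}

    def svec_index(i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        return j * (j + 1) // 2 + i

    eq_b = _RowBuilder(dim, svec_dim, svec_index)
    in_b = _RowBuilder(dim, svec_dim, svec_index)

    # normalization Z00 = 1
    eq_b.add({(0, 0): 1.0}, 1.0)

    pair_set: set[Tuple[int, int]] = set()
    for eq in quadsys.equalities:
        entries, const = _scaled_quadratic_entries(
            eq, var_index, lows, widths, fixed)
        entries[(0, 0)] = entries.get((0, 0), 0.0) + const
        eq_b.add(entries, 0.0)
        for (i, j) in entries:
            if 1 <= i < j:
                pair_set.add((i - 1, j - 1))

    for lin in quadsys.inequalities:
        entries = {}
        rhs = lin.rhs
        for v, c in lin.coeffs.items():
            if v in fixed:
                rhs -= c * fixed[v]
            else:
                i = var_index[v] + 1
                entries[(0, i)] = entries.get((0, i), 0.0) + c * widths[v] / 2
                rhs -= c * lows[v]
        in_b.add(entries, rhs)

    # bounds on scaled variables: 0 <= ζ_i <= 1
    for i in range(1, dim):
        in_b.add({(0, i): -0.5}, 0.0)
        in_b.add({(0, i): 0.5}, 1.0)

    # diagonal RLT: ζ_i(1−ζ_i) >= 0 and (1−ζ_i)^2 >= 0
    for i in range(1, dim):
        in_b.add({(i, i): 1.0, (0, i): -0.5}, 0.0)
        in_b.add({(i, i): -1.0, (0, i): 1.0}, 1.0)

    if rlt_level == "full":
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    elif rlt_level == "pairs":
        pairs = sorted(pair_set)
    else:
        pairs = []
    for (a, b) in pairs:
        i, j = a + 1, b + 1
        # ζ_i ζ_j >= 0 ; ζ_i(1−ζ_j) >= 0 ; ζ_j(1−ζ_i) >= 0 ;
        # (1−ζ_i)(1−ζ_j) >= 0
        in_b.add({(i, j): -0.5}, 0.0)
        in_b.add({(i, j): 0.5, (0, i): -0.5}, 0.0)
        in_b.add({(i, j): 0.5, (0, j): -0.5}, 0.0)
        in_b.add({(i, j): -0.5, (0, i): 0.5, (0, j): 0.5}, 1.0)

    A_eq, b_eq = eq_b.to_sparse()
    A_in, b_in = in_b.to_sparse()
    return SDPRelaxation(
        variables=tuple(free),
        lows=np.array([lows[v] for v in free]),
        widths=np.array([widths[v] for v in free]),
        fixed=fixed, n=n, dim=dim, svec_dim=svec_dim,
        A_eq=A_eq, b_eq=b_eq, A_in=A_in, b_in=b_in,
        rlt_level=rlt_level, rlt_pairs=pairs,
        infeasible_by_construction=quadsys.infeasible_by_construction)
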