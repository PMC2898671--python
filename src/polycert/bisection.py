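"""Bisection exploration of the parameter box with certified discarding.

The outer-approximation algorithm recursively splits the parameter box,
discards every sub-box carrying a validated infeasibility certificate, and
keeps every sub-box whose relative size has fallen below the precision
threshold ε without being certified.  The union of kept boxes is a
guaranteed outer approximation of the consistent parameter set: a validated
certificate can never discard a truly consistent parameter, so no valid
parameterization is lost.

A cheap forward-simulation probe searches boxes for feasible points before
any SDP is attempted: a box with a verified feasible point can never be
discarded, so the (expensive) certificate call is skipped for it.  Probing
never discards — it only avoids work inside feasible regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .certificates import certify_instance
from .feasibility import build_feasibility_instance
from .model import DifferenceSystem
from .poly import Interval
from .sets import Box, InputSequence, MeasurementSequence

KEEP_EPSILON = "eps-reached"
KEEP_FEASIBLE = "feasible-point"
KEEP_BUDGET = "budget-exhausted"


@dataclass
class EstimationConfig:
    """Tunable knobs of the outer-approximation algorithm."""

    eps: float = 0.05                 # relative precision of kept boxes
    rlt_level: str = "pairs"
    max_depth: int = 60
    max_sdp_solves: Optional[int] = None
    sdp_max_iters: int = 20000
    sdp_check_every: int = 100
    sdp_feas_tol: float = 1e-6
    probe_samples: int = 20
    probe_polish: bool = True
    probe_polish_maxiter: int = 300
    probe_polish_restarts: int = 1
    frozen_parameters: Tuple[str, ...] = ()   # bounded but never bisected
    window_length: int = 3            # measurement sub-window policy
    window_overlap: int = 1
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.eps <= 1.0):
            raise ValueError("eps must lie in (0, 1]")


@dataclass
class KeptBox:
    box: Box
    status: str


@dataclass
class OuterApproximation:
    initial_box: Box
    kept: List[KeptBox]
    discarded: List[Box]
    eps: float
    sdp_solves: int
    provenance: Dict[str, object] = field(default_factory=dict)
    budget_exhausted: bool = False

    @property
    def invalidated(self) -> bool:
        """Empty kept set: no parameter in the initial box is consistent."""
        return not self.kept

    def contains(self, point: Dict[str, float], tol: float = 1e-12) -> bool:
        return any(kb.box.contains_point(point, tol) for kb in self.kept)


def relative_size(box: Box, initial: Box,
                  dims: Optional[Sequence[str]] = None) -> float:
    """Max over bisected dimensions of width(box_i)/width(initial_i)."""
    if dims is None:
        dims = [v for v in initial.variables if initial[v].width > 0]
    if not dims:
        return 0.0
    return max(box[v].width / initial[v].width for v in dims)


def bisect_box(box: Box, initial: Box,
               dims: Optional[Sequence[str]] = None) -> Tuple[Box, Box]:
    """Split at the midpoint of the dimension with largest relative width
    (ties to the earliest dimension); the halves partition the box."""
    if dims is None:
        dims = [v for v in initial.variables if initial[v].width > 0]
    widths = [(box[v].width / initial[v].width if initial[v].width > 0
               else 0.0) for v in dims]
    if not widths or max(widths) == 0.0:
        raise ValueError("cannot bisect a box with no positive-width "
                         "bisection dimension")
    d = dims[int(np.argmax(widths))]
    mid = box[d].midpoint
    lo = box.replace(d, Interval(box[d].lower, mid))
    hi = box.replace(d, Interval(mid, box[d].upper))
    return lo, hi


def _shifted_state_guess(system: DifferenceSystem,
                         data: MeasurementSequence,
                         state_box: Box, k0: int) -> Dict[str, float]:
    """Initial-state guess: measurement midpoints where the observable is a
    state measured at the window start, state-box centres elsewhere."""
    guess = {st: state_box[st].midpoint for st in system.states}
    if k0 in data.sets:
        mset = data.sets[k0]
        if isinstance(mset, dict):
            for obs, iv in mset.items():
                if obs in guess:
                    guess[obs] = iv.midpoint
    return guess


def _trajectory_feasible(system: DifferenceSystem,
                         data: MeasurementSequence,
                         inputs: InputSequence, state_box: Box,
                         window: Tuple[int, int],
                         p: Dict[str, float], x0: Dict[str, float],
                         tol: float = 1e-9) -> bool:
    k0, k1 = window
    try:
        traj = system.simulate(x0, p, inputs, k1 - k0, start_index=k0)
    except (ArithmeticError, OverflowError, ValueError):
        return False
    for k in range(k0, k1 + 1):
        xs = traj.state_at(k)
        if not state_box.contains_point(xs, tol):
            return False
        if k in data.sets and not data.contains(k, traj.output_at(k), tol):
            return False
    return True


def probe_feasible_point(system: DifferenceSystem,
                         data: MeasurementSequence,
                         inputs: InputSequence,
                         param_box: Box, state_box: Box,
                         window: Tuple[int, int],
                         rng: np.random.Generator,
                         n_samples: int = 20,
                         polish: bool = True,
                         polish_maxiter: int = 300,
                         polish_restarts: int = 1
                         ) -> Optional[Dict[str, float]]:
    """Search the box for a parameter/initial-state pair whose forward
    simulation satisfies every constraint of the window.  Returns the
    parameter point, or None (which proves nothing)."""
    k0, k1 = window
    guess_x0 = _shifted_state_guess(system, data, state_box, k0)
    candidates = [param_box.midpoint()] + param_box.sample(
        rng, max(0, n_samples - 1))
    for p in candidates:
        if _trajectory_feasible(system, data, inputs, state_box, window,
                                p, guess_x0):
            return p
    if not polish:
        return None

    # local search over (parameters, initial state) on the max violation
    from scipy.optimize import minimize

    p_names = list(param_box.variables)
    x_names = list(system.states)

    def unpack(z: np.ndarray) -> Tuple[Dict[str, float], Dict[str, float]]:
        p = {}
        for i, name in enumerate(p_names):
            iv = param_box[name]
            p[name] = float(np.clip(z[i], iv.lower, iv.upper))
        x0 = {}
        for j, name in enumerate(x_names):
            iv = state_box[name]
            x0[name] = float(np.clip(z[len(p_names) + j], iv.lower, iv.upper))
        return p, x0

    def violation(z: np.ndarray) -> float:
        p, x0 = unpack(z)
        try:
            traj = system.simulate(x0, p, inputs, k1 - k0, start_index=k0)
        except (ArithmeticError, OverflowError, ValueError):
            return 1e6
        worst = 0.0
        for k in range(k0, k1 + 1):
            xs = traj.state_at(k)
            for st, val in xs.items():
                iv = state_box[st]
                scale = max(1.0, iv.width)
                worst = max(worst, (iv.lower - val) / scale,
                            (val - iv.upper) / scale)
            if k in data.sets:
                mset = data.sets[k]
                out = traj.output_at(k)
                if isinstance(mset, dict):
                    for obs, iv in mset.items():
                        scale = max(abs(iv.lower), abs(iv.upper), 1e-9)
                        worst = max(worst, (iv.lower - out[obs]) / scale,
                                    (out[obs] - iv.upper) / scale)
                elif not mset.contains_point(out, 0.0):
                    worst = max(worst, 1.0)
        return worst

    z0 = np.array([param_box[n].midpoint for n in p_names]
                  + [guess_x0[n] for n in x_names])
    starts = [z0]
    for _ in range(max(0, polish_restarts - 1)):
        p_rand = param_box.sample(rng, 1)[0]
        x_rand = [guess_x0[n] + 0.3 * state_box[n].width
                  * rng.standard_normal() for n in x_names]
        starts.append(np.array([p_rand[n] for n in p_names] + x_rand))
    for start in starts:
        res = minimize(violation, start, method="Nelder-Mead",
                       options={"maxiter": polish_maxiter, "xatol": 1e-10,
                                "fatol": 1e-12})
        p, x0 = unpack(res.x)
        if _trajectory_feasible(system, data, inputs, state_box, window,
                                p, x0):
            return p
    return None


def outer_approximate(system: DifferenceSystem,
                      data: MeasurementSequence,
                      inputs: InputSequence,
                      param_box: Box,
                      state_box: Box,
                      config: EstimationConfig,
                      window: Optional[Tuple[int, int]] = None,
                      stop_when_kept: bool = False) -> OuterApproximation:
    """Algorithm: certified-discard bisection over the parameter box.

    Depth-first with the lower half explored first, so runs are
    deterministic.  With `stop_when_kept` the exploration returns as soon
    as one box is kept (enough to conclude "not invalidated").
    """
    if window is None:
        window = data.window
    rng = np.random.default_rng(config.seed)
    dims = [v for v in param_box.variables
            if param_box[v].width > 0 and v not in config.frozen_parameters]

    kept: List[KeptBox] = []
    discarded: List[Box] = []
    solves = 0
    budget_exhausted = False

    stack: List[Tuple[Box, int]] = [(param_box, 0)]
    while stack:
        box, depth = stack.pop()
        size = relative_size(box, param_box, dims)
        feasible_p = probe_feasible_point(
            system, data, inputs, box, state_box, window, rng,
            n_samples=config.probe_samples, polish=config.probe_polish,
            polish_maxiter=config.probe_polish_maxiter,
            polish_restarts=config.probe_polish_restarts)
        if feasible_p is None:
            if (config.max_sdp_solves is not None
                    and solves >= config.max_sdp_solves):
                kept.append(KeptBox(box, KEEP_BUDGET))
                budget_exhausted = True
                if stop_when_kept:
                    break
                continue
            inst = build_feasibility_instance(
                system, data, inputs, box, state_box, window)
            result = certify_instance(
                inst, rlt_level=config.rlt_level,
                max_iters=config.sdp_max_iters,
                check_every=config.sdp_check_every,
                feas_tol=config.sdp_feas_tol)
            solves += 1
            if result.certified:
                discarded.append(box)
                continue
        if size <= config.eps or not dims:
            kept.append(KeptBox(
                box, KEEP_FEASIBLE if feasible_p is not None
                else KEEP_EPSILON))
            if stop_when_kept:
                break
            continue
        if depth >= config.max_depth:
            kept.append(KeptBox(box, KEEP_BUDGET))
            budget_exhausted = True
            if stop_when_kept:
                break
            continue
        lo, hi = bisect_box(box, param_box, dims)
        stack.append((hi, depth + 1))
        stack.append((lo, depth + 1))

    return OuterApproximation(
        initial_box=param_box, kept=kept, discarded=discarded,
        eps=config.eps, sdp_solves=solves,
        provenance={"window": window, "model": system.name},
        budget_exhausted=budget_exhausted)


def single_parameter_bounds(system: DifferenceSystem,
                            data: MeasurementSequence,
                            inputs: InputSequence,
                            param_box: Box,
                            state_box: Box,
                            parameter: str,
                            config: EstimationConfig,
                            window: Optional[Tuple[int, int]] = None
                            ) -> Tuple[Optional[Interval], int]:
    """Bounding interval for one parameter: bisect only that coordinate,
    leaving all others at their full prior box.  Returns (hull of the kept
    leaves, SDP solve count); the hull is None if every leaf was certified
    inconsistent (the data invalidate the whole prior box)."""
    sub = EstimationConfig(**{**config.__dict__,
                              "frozen_parameters": tuple(
                                  v for v in param_box.variables
                                  if v != parameter)})
    approx = outer_approximate(system, data, inputs, param_box, state_box,
                               sub, window=window)
    if approx.invalidated:
        return None, approx.sdp_solves
    lo = min(kb.box[parameter].lower for kb in approx.kept)
    hi = max(kb.box[parameter].upper for kb in approx.kept)
    return Interval(lo, hi), approx.sdp_solves


def intersect_approximations(approxs: Sequence[OuterApproximation]
                             ) -> OuterApproximation:
    """Box-wise intersection of kept unions (estimates from measurement
    sub-windows of a common dataset can be combined this way)."""
    if not approxs:
        raise ValueError("nothing to intersect")
    first = approxs[0]
    for other in approxs[1:]:
        if other.initial_box != first.initial_box:
            raise ValueError("approximations have different initial boxes")
    kept = list(first.kept)
    for other in approxs[1:]:
        new: List[KeptBox] = []
        for ka in kept:
            for kb in other.kept:
                cap = ka.box.intersect(kb.box)
                if cap is not None:
                    status = (KEEP_FEASIBLE
                              if KEEP_FEASIBLE in (ka.status, kb.status)
                              else KEEP_EPSILON)
                    new.append(KeptBox(cap, status))
        kept = new
    return OuterApproximation(
        initial_box=first.initial_box, kept=kept, discarded=[],
        eps=max(a.eps for a in approxs),
        sdp_solves=sum(a.sdp_solves for a in approxs),
        provenance={"intersection_of": len(approxs)},
        budget_exhausted=any(a.budget_exhausted for a in approxs))


def project_bounds(approx: OuterApproximation
                   ) -> Optional[Dict[str, Interval]]:
    """Coordinate-wise hull of the kept union (single-parameter
    projections); None when the kept set is empty (model invalidated)."""
    if approx.invalidated:
        return None
    out: Dict[str, Interval] = {}
    for v in approx.initial_box.variables:
        out[v] = Interval(min(kb.box[v].lower for kb in approx.kept),
                          max(kb.box[v].upper for kb in approx.kept))
    return out
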