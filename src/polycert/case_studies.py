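"""Case studies: Michaelis-Menten vs Henri discrimination and the carnitine
shuttle estimation scenarios, plus the synthetic interval-data generator and
a Monte Carlo consistency sampler.

The synthetic data emulate set-bounded measurements of forward-simulated
trajectories: at each requested time index and measured observable the
interval [y(1−σ), y(1+σ)] is recorded, σ being the relative measurement
half-width.  These are the study conditions under which invalidation
thresholds and parameter bounds are computed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bisection import (EstimationConfig, OuterApproximation,
                        intersect_approximations, outer_approximate,
                        probe_feasible_point, project_bounds)
from .feasibility import split_measurements, split_runs
from .io import ModelConfig, ReferenceSetup, load_model_config
from .model import DifferenceSystem, Trajectory, discretize_euler, ode_rhs
from .poly import Interval
from .sets import Box, InputSequence, MeasurementSequence

CASE_MODELS = ("mm", "henri", "carnitine")

# scenario axes (full factorial: 2 x 2 x 3 x 4 = 48)
PRIORS = ("3-PAR", "5-PAR")
DENSITIES = ("DENSE", "SPARSE")
ERRORS = (0.01, 0.02, 0.04)
MEASURED_OPTIONS = ("ALL", "NOT-X3", "NOT-X4", "NOT-X3-X4")

DENSE_INDEXES = tuple(range(0, 15)) + tuple(range(300, 315))
SPARSE_INDEXES = (0, 3, 5, 10, 14, 300, 303, 305, 310, 314)

# parameters known a priori in the 3-PAR setting, with tight relative bounds
KNOWN_3PAR = ("p1", "p5")
KNOWN_REL_BOUNDS = (0.95, 1.05)
UNKNOWN_REL_BOUNDS = (0.5, 2.0)


def case_model_config(name: str) -> ModelConfig:
    """Load one of the shipped model configs (mm, henri, carnitine)."""
    if name not in CASE_MODELS:
        raise ValueError(f"unknown case model '{name}'")
    ref = importlib.resources.files("polycert.models") / f"{name}.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_model_config(path)


def build_case_model(name: str,
                     h: Optional[float] = None
                     ) -> Tuple[DifferenceSystem, ModelConfig]:
    """Difference system of a shipped case study at its (or a given) step."""
    cfg = case_model_config(name)
    ode = ode_rhs(cfg.network)
    system = discretize_euler(ode, h if h is not None else cfg.h,
                              state_box=cfg.state_box,
                              param_box=cfg.param_box)
    return system, cfg


@dataclass(frozen=True)
class Scenario:
    prior: str        # 3-PAR | 5-PAR
    density: str      # DENSE | SPARSE
    error: float      # relative measurement half-width (0.01, 0.02, 0.04)
    measured: str     # ALL | NOT-X3 | NOT-X4 | NOT-X3-X4

    def __post_init__(self) -> None:
        if self.prior not in PRIORS or self.density not in DENSITIES \
                or self.error not in ERRORS \
                or self.measured not in MEASURED_OPTIONS:
            raise ValueError(f"invalid scenario {self}")

    @property
    def indexes(self) -> Tuple[int, ...]:
        return DENSE_INDEXES if self.density == "DENSE" else SPARSE_INDEXES

    @property
    def observables(self) -> Tuple[str, ...]:
        excluded = {"NOT-X3": {"x3"}, "NOT-X4": {"x4"},
                    "NOT-X3-X4": {"x3", "x4"}}.get(self.measured, set())
        return tuple(x for x in ("x1", "x2", "x3", "x4")
                     if x not in excluded)

    def label(self) -> str:
        return (f"({self.prior}, {self.density}, {self.measured}, "
                f"ERR-{self.error * 100:g}%)")


def enumerate_scenarios() -> List[Scenario]:
    """The full factorial grid of experimental scenarios."""
    return [Scenario(p, d, e, m)
            for p in PRIORS for d in DENSITIES
            for e in ERRORS for m in MEASURED_OPTIONS]


def generate_measurements(traj: Trajectory, indexes: Sequence[int],
                          sigma: float,
                          measured: Optional[Sequence[str]] = None
                          ) -> MeasurementSequence:
    """Relative interval measurements y·[1−σ, 1+σ] of a trajectory."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    obs_names = list(measured) if measured is not None else list(traj.outputs)
    sets: Dict[int, Dict[str, Interval]] = {}
    for k in indexes:
        if k not in traj.indexes:
            raise ValueError(f"index {k} not in trajectory")
        out = traj.output_at(k)
        row = {}
        for obs in obs_names:
            y = out[obs]
            if y < 0:
                raise ValueError(
                    f"negative output {obs}={y} at index {k}; relative "
                    "intervals assume non-negative concentrations")
            row[obs] = Interval(y * (1.0 - sigma), y * (1.0 + sigma))
        sets[int(k)] = row
    return MeasurementSequence(sets)


def scenario_param_box(scenario: Scenario, reference: ReferenceSetup) -> Box:
    """Prior parameter box: tight relative bounds around p* for the known
    parameters of the 3-PAR setting, loose relative bounds otherwise."""
    bounds = {}
    for name, pstar in reference.parameters.items():
        if scenario.prior == "3-PAR" and name in KNOWN_3PAR:
            lo, hi = KNOWN_REL_BOUNDS
        else:
            lo, hi = UNKNOWN_REL_BOUNDS
        bounds[name] = Interval(pstar * lo, pstar * hi)
    return Box(bounds)


def scenario_frozen_parameters(scenario: Scenario) -> Tuple[str, ...]:
    return KNOWN_3PAR if scenario.prior == "3-PAR" else ()


# -- invalidation scan (model discrimination) -------------------------


def invalidated_at(null_system: DifferenceSystem,
                   data: MeasurementSequence,
                   inputs: InputSequence,
                   param_box: Box, state_box: Box,
                   config: EstimationConfig,
                   scan_window_length: int = 7) -> bool:
    """Decide whether the data conclusively invalidate the null model.

    Cheap steps first: a feasibility probe (a feasible point proves
    consistency), then whole-box certificates on short measurement
    sub-windows and on the full window, and finally the bisection
    algorithm on the full window (an empty kept set proves invalidity).
    """
    from .certificates import certify_instance
    from .feasibility import build_feasibility_instance

    window = data.window
    rng = np.random.default_rng(config.seed)
    # cheap sampling probe first: a feasible point settles the question
    if probe_feasible_point(null_system, data, inputs, param_box, state_box,
                            window, rng, n_samples=config.probe_samples,
                            polish=False):
        return False
    for sub in split_measurements(data, scan_window_length, 1):
        inst = build_feasibility_instance(
            null_system, sub, inputs, param_box, state_box)
        if certify_instance(inst, rlt_level=config.rlt_level,
                            max_iters=config.sdp_max_iters,
                            check_every=config.sdp_check_every).certified:
            return True
    # no quick certificate: spend effort on a polished feasibility search
    if config.probe_polish and probe_feasible_point(
            null_system, data, inputs, param_box, state_box, window, rng,
            n_samples=0, polish=True,
            polish_maxiter=config.probe_polish_maxiter,
            polish_restarts=config.probe_polish_restarts):
        return False
    if len(data) > scan_window_length:
        inst = build_feasibility_instance(
            null_system, data, inputs, param_box, state_box)
        if certify_instance(inst, rlt_level=config.rlt_level,
                            max_iters=config.sdp_max_iters,
                            check_every=config.sdp_check_every).certified:
            return True
    approx = outer_approximate(null_system, data, inputs, param_box,
                               state_box, config, stop_when_kept=True)
    return approx.invalidated and not approx.budget_exhausted


def run_invalidation_scan(null_system: DifferenceSystem,
                          reference_system: DifferenceSystem,
                          reference: ReferenceSetup,
                          x0: Dict[str, float],
                          param_box: Box, state_box: Box,
                          config: EstimationConfig,
                          sigma_grid: Optional[Sequence[float]] = None,
                          ) -> Optional[float]:
    """Largest σ on the grid at which the null model is invalidated by
    interval data generated from the reference model started at x0.

    The grid is scanned in ascending order and stops at the first σ that
    fails to invalidate (the feasible set only grows with σ).  Returns
    None if even the smallest σ admits a consistent parameterization.
    """
    if sigma_grid is None:
        sigma_grid = default_sigma_grid()
    inputs = InputSequence.constant(reference.inputs)
    traj = reference_system.simulate(x0, reference.parameters, inputs,
                                     reference.horizon)
    largest = None
    for sigma in sigma_grid:
        data = generate_measurements(traj, traj.indexes, sigma)
        if invalidated_at(null_system, data, inputs, param_box, state_box,
                          config):
            largest = sigma
        else:
            break
    return largest


def default_sigma_grid(lo: float = 0.005, hi: float = 0.20,
                       step: float = 0.005) -> List[float]:
    """0.5% steps from 0.5% to 20%."""
    n = int(round((hi - lo) / step)) + 1
    return [round(lo + i * step, 10) for i in range(n)]


# Initial conditions of the discrimination study, ordered from far-from-
# steady-state (large certified error) to near-steady-state.
DISCRIMINATION_INITIAL_CONDITIONS = (
    (0.999, 0.001), (0.990, 0.010), (0.900, 0.100), (0.800, 0.100),
    (0.800, 0.200), (0.700, 0.300), (0.600, 0.400))


# -- scenario estimation ----------------------------------------------


@dataclass
class ScenarioResult:
    scenario: Scenario
    bounds: Optional[Dict[str, Interval]]
    relative_bounds: Optional[Dict[str, Tuple[float, float]]]
    initial_box: Box
    invalidated: bool
    sdp_solves: int
    approximation: Optional[OuterApproximation] = None

    def contains(self, point: Dict[str, float], tol: float = 1e-12) -> bool:
        if self.bounds is None:
            return False
        return all(iv.contains(point[name], tol)
                   for name, iv in self.bounds.items())


def run_scenario(scenario: Scenario,
                 config: EstimationConfig,
                 reference: Optional[ReferenceSetup] = None,
                 mode: str = "bounding-box",
                 estimate_parameters: Optional[Sequence[str]] = None,
                 phases: str = "all"
                 ) -> ScenarioResult:
    """Estimate carnitine-shuttle parameter bounds for one scenario.

    Data are generated from the reference simulation, split into the
    transient and equilibrium runs and then into short overlapping
    sub-windows, and the per-window estimates are intersected.

    In the default ``bounding-box`` mode each non-frozen parameter is
    bounded separately per window (bisecting only that coordinate, the
    others spanning their full prior box) — the polynomial-time bounding
    box of the consistent set, and the form in which per-parameter results
    are reported.  ``full`` mode bisects the whole parameter box instead.
    `estimate_parameters` restricts bounding-box estimation to a subset
    (the others keep their prior bounds); `phases` selects which
    measurement runs to use ("all", "transient" or "equilibrium").
    """
    from .bisection import single_parameter_bounds

    system, cfg = build_case_model("carnitine")
    if reference is None:
        reference = cfg.reference
    inputs = InputSequence.constant(reference.inputs)
    traj = system.simulate(reference.x0, reference.parameters, inputs,
                           reference.horizon)
    data = generate_measurements(traj, scenario.indexes, scenario.error,
                                 scenario.observables)
    param_box = scenario_param_box(scenario, reference)
    frozen = scenario_frozen_parameters(scenario)
    config = replace(config, frozen_parameters=frozen)

    runs = split_runs(data)
    if phases == "transient":
        runs = runs[:1]
    elif phases == "equilibrium":
        runs = runs[-1:]
    elif phases != "all":
        raise ValueError(f"unknown phases option '{phases}'")
    windows = [sub for run in runs
               for sub in split_measurements(
                   data=run, window_length=config.window_length,
                   overlap=config.window_overlap)]

    if mode == "full":
        approxs = [outer_approximate(system, sub, inputs, param_box,
                                     cfg.state_box, config)
                   for sub in windows]
        approx = intersect_approximations(approxs)
        bounds = project_bounds(approx)
        result = ScenarioResult(
            scenario=scenario, bounds=bounds, relative_bounds=None,
            initial_box=param_box, invalidated=approx.invalidated,
            sdp_solves=approx.sdp_solves, approximation=approx)
    elif mode == "bounding-box":
        free = [p for p in param_box.variables if p not in frozen]
        if estimate_parameters is not None:
            free = [p for p in free if p in estimate_parameters]
        bounds: Optional[Dict[str, Interval]] = {
            p: param_box[p] for p in param_box.variables}
        solves = 0
        invalidated = False
        for sub in windows:
            for p in free:
                est = single_parameter_bounds(
                    system, sub, inputs, param_box, cfg.state_box, p,
                    config)
                solves += est[1]
                if est[0] is None:
                    invalidated = True
                    bounds = None
                    break
                cap = bounds[p].intersect(est[0])
                if cap is None:
                    invalidated = True
                    bounds = None
                    break
                bounds[p] = cap
            if invalidated:
                break
        result = ScenarioResult(
            scenario=scenario, bounds=bounds, relative_bounds=None,
            initial_box=param_box, invalidated=invalidated,
            sdp_solves=solves)
    else:
        raise ValueError(f"unknown mode '{mode}'")

    if result.bounds is not None:
        result.relative_bounds = {
            name: (iv.lower / reference.parameters[name],
                   iv.upper / reference.parameters[name])
            for name, iv in result.bounds.items()}
    return result


# -- Monte Carlo consistency sampling ---------------------------------


def mc_consistency_sample(system: DifferenceSystem,
                          data: MeasurementSequence,
                          inputs: InputSequence,
                          param_box: Box, state_box: Box,
                          n: int, seed: int,
                          x0_samples: int = 5) -> List[Dict[str, float]]:
    """Uniform parameter samples kept iff some forward simulation (initial
    state from the first measurement, else sampled from the state box)
    satisfies every measurement and bound constraint; deterministic for a
    given seed."""
    if n <= 0:
        raise ValueError("n must be positive")
    from .bisection import _shifted_state_guess, _trajectory_feasible

    rng = np.random.default_rng(seed)
    window = data.window
    k0 = window[0]
    kept: List[Dict[str, float]] = []
    for p in param_box.sample(rng, n):
        guesses = [_shifted_state_guess(system, data, state_box, k0)]
        guesses.extend(state_box.sample(rng, x0_samples))
        if any(_trajectory_feasible(system, data, inputs, state_box,
                                    window, p, g) for g in guesses):
            kept.append(p)
    return kept
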