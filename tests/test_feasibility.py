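"""Feasibility-problem assembly, measurement windowing and residual checks."""

import numpy as np
import pytest

from polycert import (Box, InputSequence, Interval, MeasurementSequence,
                      build_feasibility_instance, generate_measurements,
                      residual_check, split_measurements, split_runs)
from polycert.feasibility import timed


def _mm_data(mm, henri_trajectory, sigma=0.01):
    return generate_measurements(henri_trajectory,
                                 henri_trajectory.indexes, sigma)


def test_instance_counts_for_full_mm_window(mm, henri_trajectory):
    """21 measured indexes and 2 states: 2·21 state variables + 3
    parameters, 20·2 step equalities; interval measurements of bare states
    are realized as tightened variable bounds."""
    system, cfg = mm
    data = _mm_data(mm, henri_trajectory)
    inst = build_feasibility_instance(system, data, InputSequence.constant({}),
                                      cfg.param_box, cfg.state_box,
                                      contract_bounds=False)
    assert len(inst.variables) == 2 * 21 + 3
    assert len(inst.equalities) == 20 * 2
    for k in data.indexes:
        for obs, iv in data.sets[k].items():
            bound = inst.bounds[timed(obs, k)]
            expected = iv.intersect(cfg.state_box[obs])
            assert bound.lower == pytest.approx(expected.lower)
            assert bound.upper == pytest.approx(expected.upper)


def test_degenerate_window_has_no_dynamics():
    from polycert import Reaction, ReactionNetwork, discretize_euler, ode_rhs
    net = ReactionNetwork(("A",), [Reaction({"A": 1}, {}, "p")], ("p",))
    system = discretize_euler(ode_rhs(net), 0.5)
    data = MeasurementSequence({0: {"A": Interval(0.4, 0.6)}})
    inst = build_feasibility_instance(
        system, data, InputSequence.constant({}),
        Box({"p": (0, 1)}), Box({"A": (0, 1)}))
    assert inst.equalities == []
    assert inst.bounds["A@0"].lower == pytest.approx(0.4)


def test_generating_assignment_is_feasible(mm, henri_trajectory, henri):
    """The reference trajectory with its generating parameters satisfies
    the instance built from its own interval data."""
    h_system, h_cfg = henri
    data = generate_measurements(henri_trajectory,
                                 henri_trajectory.indexes, 0.01)
    inst = build_feasibility_instance(
        h_system, data, InputSequence.constant({}), h_cfg.param_box,
        h_cfg.state_box)
    assignment = dict(h_cfg.reference.parameters)
    for k in henri_trajectory.indexes:
        for st, val in henri_trajectory.state_at(k).items():
            assignment[timed(st, k)] = val
    ok, viol = residual_check(inst, assignment)
    assert ok and viol < 1e-9


def test_wrong_parameter_violates(mm, henri, henri_trajectory):
    h_system, h_cfg = henri
    data = generate_measurements(henri_trajectory,
                                 henri_trajectory.indexes, 0.01)
    inst = build_feasibility_instance(
        h_system, data, InputSequence.constant({}), h_cfg.param_box,
        h_cfg.state_box)
    p_wrong = {"p1": 2.0, "p2": 1.0, "p3": 1.0}
    traj = h_system.simulate({"S": 0.999, "C": 0.001}, p_wrong,
                             InputSequence.constant({}), 20)
    assignment = dict(p_wrong)
    for k in traj.indexes:
        for st, val in traj.state_at(k).items():
            assignment[timed(st, k)] = val
    ok, viol = residual_check(inst, assignment)
    assert not ok and viol > 0


def test_empty_constraint_set_passes():
    from polycert.feasibility import FeasibilityInstance
    inst = FeasibilityInstance(variables=(), bounds={}, equalities=[],
                               inequalities=[], window=(0, 0))
    ok, viol = residual_check(inst, {})
    assert ok and viol == 0.0


def test_unmeasured_observable_imposes_no_constraint(carnitine):
    """NOT-X3 style data leave the x3 trajectory variables bounded only by
    the prior state box (after contraction they may tighten, but never
    through a measurement row)."""
    system, cfg = carnitine
    ref = cfg.reference
    traj = system.simulate(ref.x0, ref.parameters,
                           InputSequence.constant(ref.inputs), 5)
    data = generate_measurements(traj, [0, 3, 5], 0.01,
                                 ["x1", "x2", "x4"])
    inst = build_feasibility_instance(
        system, data, InputSequence.constant(ref.inputs), cfg.param_box,
        cfg.state_box, contract_bounds=False)
    for k in (0, 3, 5):
        assert inst.bounds[timed("x3", k)] == cfg.state_box["x3"]


def test_measurement_outside_window_rejected(decay_toy):
    system, make_data = decay_toy
    data = make_data(0.5, 1.0, 5, 0.1)
    with pytest.raises(ValueError, match="outside"):
        build_feasibility_instance(
            system, data, InputSequence.constant({}), Box({"p": (0, 1)}),
            Box({"A": (0, 2)}), window=(0, 3))


def test_split_measurements_examples():
    data = MeasurementSequence(
        {k: {"y": Interval(0, 1)} for k in (0, 3, 5, 10, 14)})
    subs = split_measurements(data, 2, 1)
    assert [s.indexes for s in subs] == [[0, 3], [3, 5], [5, 10], [10, 14]]
    assert split_measurements(data, 5, 1)[0].indexes == data.indexes
    assert len(split_measurements(data, 9, 1)) == 1  # longer than data


def test_split_runs_separates_transient_and_equilibrium():
    idx = list(range(0, 15)) + list(range(300, 315))
    data = MeasurementSequence({k: {"y": Interval(0, 1)} for k in idx})
    runs = split_runs(data)
    assert [r.indexes[0] for r in runs] == [0, 300]
    assert [len(r) for r in runs] == [15, 15]


def test_feasible_set_monotone_in_sigma(henri, henri_trajectory, rng):
    """Any assignment feasible for the tighter (small σ) instance is
    feasible for the looser one."""
    h_system, h_cfg = henri
    small = generate_measurements(henri_trajectory,
                                  henri_trajectory.indexes, 0.01)
    large = generate_measurements(henri_trajectory,
                                  henri_trajectory.indexes, 0.05)
    inst_s = build_feasibility_instance(
        h_system, small, InputSequence.constant({}), h_cfg.param_box,
        h_cfg.state_box)
    inst_l = build_feasibility_instance(
        h_system, large, InputSequence.constant({}), h_cfg.param_box,
        h_cfg.state_box)
    for _ in range(20):
        p = {n: rng.uniform(0.8, 1.2) for n in ("p1", "p2", "p3")}
        x0 = {"S": rng.uniform(0.99, 1.0), "C": rng.uniform(0.0, 0.01)}
        traj = h_system.simulate(x0, p, InputSequence.constant({}), 20)
        assignment = dict(p)
        for k in traj.indexes:
            for st, val in traj.state_at(k).items():
                assignment[timed(st, k)] = val
        if residual_check(inst_s, assignment)[0]:
            assert residual_check(inst_l, assignment)[0]


def test_window_restriction_preserves_feasibility(henri, henri_trajectory):
    """An assignment feasible on the full window restricts to a feasible
    assignment of every sub-window instance."""
    h_system, h_cfg = henri
    data = generate_measurements(henri_trajectory,
                                 henri_trajectory.indexes, 0.02)
    assignment = dict(h_cfg.reference.parameters)
    for k in henri_trajectory.indexes:
        for st, val in henri_trajectory.state_at(k).items():
            assignment[timed(st, k)] = val
    for sub in split_measurements(data, 7, 2):
        inst = build_feasibility_instance(
            h_system, sub, InputSequence.constant({}), h_cfg.param_box,
            h_cfg.state_box)
        ok, _ = residual_check(inst, assignment)
        assert ok


def test_contraction_is_sound_for_generating_trajectory(carnitine):
    """Forward bound contraction never excludes the true trajectory."""
    system, cfg = carnitine
    ref = cfg.reference
    traj = system.simulate(ref.x0, ref.parameters,
                           InputSequence.constant(ref.inputs), 14)
    data = generate_measurements(traj, [0, 3, 5, 10, 14], 0.02)
    inst = build_feasibility_instance(
        system, data, InputSequence.constant(ref.inputs), cfg.param_box,
        cfg.state_box, contract_bounds=True)
    for k in range(15):
        for st, val in traj.state_at(k).items():
            assert inst.bounds[timed(st, k)].contains(val, 1e-12)
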