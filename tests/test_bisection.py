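"""Bisection outer approximation: metric, splitting, guarantees on toys."""

import numpy as np
import pytest

from polycert import (Box, EstimationConfig, InputSequence, Interval,
                      bisect_box,
                      intersect_approximations, outer_approximate,
                      project_bounds, relative_size,
                      single_parameter_bounds)
from polycert.bisection import (KEEP_FEASIBLE, OuterApproximation, KeptBox)


def test_relative_size_examples():
    initial = Box({"a": (0, 1), "b": (0, 2), "c": (0, 4)})
    assert relative_size(initial, initial) == 1.0
    halved = initial.replace("b", Interval(0, 1))
    assert relative_size(halved, initial) == 1.0       # max metric
    small = Box({"a": (0, 0.05), "b": (0, 0.1), "c": (0, 0.2)})
    assert relative_size(small, initial) == pytest.approx(0.05)


def test_bisect_box_tie_break_and_partition():
    initial = Box({"a": (0, 1), "b": (0, 1)})
    lo, hi = bisect_box(initial, initial)
    assert lo["a"].upper == 0.5 and hi["a"].lower == 0.5   # dim 0 on ties
    assert lo["b"] == initial["b"] == hi["b"]
    narrow = Box({"a": (0, 1), "b": (0, 0.2)})
    lo2, _ = bisect_box(narrow, initial)
    assert lo2["a"].upper == 0.5                            # widest relative


def test_recursive_halving_reaches_eps():
    initial = Box({"a": (0, 1), "b": (0, 1), "c": (0, 1)})
    eps = 0.05
    depth_needed = 3 * int(np.ceil(np.log2(1 / eps)))
    boxes = [initial]
    for _ in range(depth_needed):
        boxes = [half for b in boxes for half in bisect_box(b, initial)]
        if all(relative_size(b, initial) <= eps for b in boxes):
            break
    assert all(relative_size(b, initial) <= eps for b in boxes)


def _toy_setup(decay_toy, sigma, p_true=0.5):
    system, make_data = decay_toy
    data = make_data(p_true, 1.0, 6, sigma)
    return system, data


def test_outer_approximation_covers_consistent_set(decay_toy, fast_config):
    """Dense-grid oracle: every parameter whose forward simulation stays in
    all intervals lies in the kept union; the union does not extend far
    beyond the consistent set."""
    system, data = _toy_setup(decay_toy, 0.05)
    pbox, sbox = Box({"p": (0, 1)}), Box({"A": (0, 2)})
    cfg = EstimationConfig(**{**fast_config.__dict__, "eps": 0.05})
    approx = outer_approximate(system, data, InputSequence.constant({}),
                               pbox, sbox, cfg)
    assert not approx.invalidated
    grid = np.linspace(0, 1, 201)
    consistent = []
    for p in grid:
        traj = system.simulate({"A": 1.0}, {"p": p},
                               InputSequence.constant({}), 6)
        ok = all(data.sets[k]["A"].contains(traj.states["A"][k])
                 for k in data.indexes)
        if ok:
            consistent.append(p)
        if ok:
            assert approx.contains({"p": p}), p
    assert consistent, "toy setup should admit consistent parameters"
    bounds = project_bounds(approx)
    assert bounds["p"].lower >= min(consistent) - 2 * 0.05
    assert bounds["p"].upper <= max(consistent) + 2 * 0.05


def test_infeasible_data_give_empty_kept_set(decay_toy, fast_config):
    """Measurements that grow while the model can only decay are certified
    inconsistent for every parameter."""
    system, make_data = decay_toy
    from polycert import generate_measurements
    grow = make_data(0.5, 1.0, 6, 0.01)
    # shift intervals upward impossibly at a late index
    grow.sets[6] = {"A": Interval(1.5, 1.6)}
    pbox, sbox = Box({"p": (0, 1)}), Box({"A": (0, 2)})
    approx = outer_approximate(system, grow, InputSequence.constant({}),
                               pbox, sbox, fast_config)
    assert approx.invalidated and approx.kept == []


def test_single_parameter_bounds_toy(decay_toy, fast_config):
    system, data = _toy_setup(decay_toy, 0.05)
    pbox, sbox = Box({"p": (0, 1)}), Box({"A": (0, 2)})
    cfg = EstimationConfig(**{**fast_config.__dict__, "eps": 0.05})
    iv, solves = single_parameter_bounds(
        system, data, InputSequence.constant({}), pbox, sbox, "p", cfg)
    assert iv is not None
    # true consistent p range for multiplicative decay data at sigma=5%
    assert iv.lower <= 0.5 <= iv.upper
    assert iv.width < 0.45


def test_intersect_approximations():
    initial = Box({"a": (0, 1), "b": (0, 1)})
    left = OuterApproximation(
        initial_box=initial,
        kept=[KeptBox(Box({"a": (0, 0.6), "b": (0, 1)}), KEEP_FEASIBLE)],
        discarded=[], eps=0.1, sdp_solves=0)
    right = OuterApproximation(
        initial_box=initial,
        kept=[KeptBox(Box({"a": (0.4, 1), "b": (0, 1)}), KEEP_FEASIBLE)],
        discarded=[], eps=0.1, sdp_solves=0)
    cap = intersect_approximations([left, right])
    assert len(cap.kept) == 1
    assert cap.kept[0].box["a"].lower == pytest.approx(0.4)
    assert cap.kept[0].box["a"].upper == pytest.approx(0.6)
    # identical inputs: same union
    same = intersect_approximations([left, left])
    assert same.kept[0].box == left.kept[0].box
    # disjoint unions: empty
    far = OuterApproximation(
        initial_box=initial,
        kept=[KeptBox(Box({"a": (0.8, 1), "b": (0, 1)}), KEEP_FEASIBLE)],
        discarded=[], eps=0.1, sdp_solves=0)
    assert intersect_approximations([left, far]).invalidated


def test_intersect_requires_matching_initial_boxes():
    a = OuterApproximation(Box({"a": (0, 1)}), [], [], 0.1, 0)
    b = OuterApproximation(Box({"a": (0, 2)}), [], [], 0.1, 0)
    with pytest.raises(ValueError, match="initial"):
        intersect_approximations([a, b])


def test_project_bounds_loses_gaps():
    initial = Box({"a": (0, 1), "b": (0, 1)})
    approx = OuterApproximation(
        initial_box=initial,
        kept=[KeptBox(Box({"a": (0, 0.2), "b": (0, 1)}), KEEP_FEASIBLE),
              KeptBox(Box({"a": (0.6, 1), "b": (0, 1)}), KEEP_FEASIBLE)],
        discarded=[], eps=0.1, sdp_solves=0)
    bounds = project_bounds(approx)
    assert bounds["a"].lower == 0 and bounds["a"].upper == 1
    empty = OuterApproximation(initial, [], [], 0.1, 0)
    assert project_bounds(empty) is None


def test_eps_monotonicity_on_toy(decay_toy, fast_config):
    """Halving ε can only shrink the kept union (nested partitions)."""
    system, data = _toy_setup(decay_toy, 0.03)
    pbox, sbox = Box({"p": (0, 1)}), Box({"A": (0, 2)})
    unions = {}
    for eps in (0.2, 0.1):
        cfg = EstimationConfig(**{**fast_config.__dict__, "eps": eps})
        approx = outer_approximate(system, data, InputSequence.constant({}),
                                   pbox, sbox, cfg)
        unions[eps] = approx
    for p in np.linspace(0, 1, 101):
        if unions[0.1].contains({"p": p}):
            assert unions[0.2].contains({"p": p})


def test_generating_parameter_always_kept(decay_toy, fast_config, rng):
    """The guarantee on the toy: the generating parameter is never lost."""
    system, make_data = decay_toy
    pbox, sbox = Box({"p": (0, 1)}), Box({"A": (0, 2)})
    for _ in range(10):
        p_true = float(rng.uniform(0.1, 0.9))
        sigma = float(rng.choice([0.01, 0.02, 0.04]))
        data = make_data(p_true, 1.0, 6, sigma)
        approx = outer_approximate(system, data,
                                   InputSequence.constant({}), pbox, sbox,
                                   fast_config)
        assert approx.contains({"p": p_true})
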