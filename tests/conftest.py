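import numpy as np
import pytest

from polycert import (EstimationConfig, FeasibilityInstance,
                      InputSequence, Interval, Polynomial,
                      build_case_model, generate_measurements)


@pytest.fixture(scope="session")
def henri():
    system, cfg = build_case_model("henri")
    return system, cfg


@pytest.fixture(scope="session")
def mm():
    system, cfg = build_case_model("mm")
    return system, cfg


@pytest.fixture(scope="session")
def carnitine():
    system, cfg = build_case_model("carnitine")
    return system, cfg


@pytest.fixture(scope="session")
def henri_trajectory(henri):
    system, cfg = henri
    return system.simulate({"S": 0.999, "C": 0.001},
                           cfg.reference.parameters,
                           InputSequence.constant({}), 20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Desk-scale estimation settings used throughout the unit tests."""
    return EstimationConfig(eps=0.25, rlt_level="pairs", sdp_max_iters=3000,
                            sdp_check_every=100, probe_samples=10,
                            probe_polish_maxiter=120, seed=1)


def cascade_instance(x1_interval, p_interval=(0.0, 1.0)):
    """Toy linear cascade x1 = p * x0 with x0 fixed to 1 and a
    measurement interval on x1."""
    variables = ("x0", "x1", "p")
    g = (Polynomial.variable(variables, "x1")
         - Polynomial.variable(variables, "p")
         * Polynomial.variable(variables, "x0"))
    return FeasibilityInstance(
        variables=variables,
        bounds={"x0": Interval(1.0, 1.0),
                "x1": Interval(*x1_interval),
                "p": Interval(*p_interval)},
        equalities=[g], inequalities=[], window=(0, 1))


@pytest.fixture
def decay_toy():
    """One-parameter decay model x_{k+1} = (1 - h p) x_k as a
    DifferenceSystem, with helpers to build interval data."""
    from polycert import ReactionNetwork, Reaction, discretize_euler, ode_rhs

    net = ReactionNetwork(species=("A",),
                          reactions=[Reaction({"A": 1}, {}, "p")],
                          parameters=("p",), name="decay")
    system = discretize_euler(ode_rhs(net), 0.5)

    def make_data(p_true, x0, K, sigma):
        traj = system.simulate({"A": x0}, {"p": p_true},
                               InputSequence.constant({}), K)
        return generate_measurements(traj, traj.indexes, sigma)

    return system, make_data
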