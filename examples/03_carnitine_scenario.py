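"""Parameter bounds for the carnitine shuttle under one measurement scenario.

Runs the set-based estimator on synthetic interval data of the
four-state carnitine shuttle (fatty-acid transport across the inner
mitochondrial membrane): dense transient + equilibrium sampling, 1%
relative error, all concentrations measured, with the supply and
mitochondrial-transferase rates (p1, p5) known to within 5%.  The data are
split into short overlapping windows; each window's single-parameter
bounds are intersected.
"""

from polycert import EstimationConfig
from polycert.case_studies import Scenario, run_scenario

scenario = Scenario(prior="3-PAR", density="DENSE", error=0.01,
                    measured="ALL")
config = EstimationConfig(eps=0.25, seed=1, sdp_max_iters=2000,
                          probe_polish_maxiter=120)
result = run_scenario(scenario, config)

print(f"scenario: {scenario.label()}")
print(f"SDP solves: {result.sdp_solves}")
print("relative parameter bounds (1.0 = generating value):")
for name, (lo, hi) in sorted(result.relative_bounds.items()):
    print(f"  {name}: [{lo:.3f}, {hi:.3f}]")
# p1 and p5 keep their prior [0.95, 1.05]; the antiporter chain rates are
# narrowed by the data, every interval is guaranteed to contain the
# generating value.
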