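# Carnitine shuttle (fatty-acid transport across the inner mitochondrial
# membrane).  States: x1 = CoA~FA (cytosol), x2 = free carnitine (cytosol),
# x3 = CoA~FA (mitochondria), x4 = free carnitine (mitochondria).
# Reactions: activated fatty-acid supply (p1, gated by beta-oxidation
# activity u), cytosolic carnitine-acyltransferase x1 + x2 <-> C~FA (p2,
# p3) with the cytosolic complex eliminated by carnitine conservation
# C~FA = C0 - x2, the antiporter C~FA + x4 -> x2 + [C~FA]_mi (p4), and the
# mitochondrial transferase regenerating CoA~FA from the imported complex
# pool (C0mi - x4) at rate p5 (the only reaction involving p5, and it only
# drives x3).  Units: μM and seconds.
name: carnitine
species: [x1, x2, x3, x4, cfa_cy]
parameters: [p1, p2, p3, p4, p5]
inputs: [u]
constants:
  C0: 0.33
  C0mi: 1.00
reactions:
  - name: fa-activation
    reactants: {}
    products: {x1: 1}
    forward: p1
    input: u
  - name: cytosolic-transferase
    reactants: {x1: 1, x2: 1}
    products: {cfa_cy: 1}
    forward: p2
    reverse: p3
  - name: antiporter
    reactants: {cfa_cy: 1, x4: 1}
    products: {x2: 1}
    forward: p4
  - name: mitochondrial-transferase
    reactants: {}
    products: {x3: 1}
    forward: p5
    prefactor: {"1": C0mi, x4: -1.0}
substitutions:
  cfa_cy: {"1": C0, x2: -1.0}
h: 5.0
param_box:
  p1: [2.5e-4, 1.0e-3]
  p2: [5.15e-2, 2.06e-1]
  p3: [1.18e-2, 4.72e-2]
  p4: [9.25e-3, 3.70e-2]
  p5: [1.25e-2, 5.00e-2]
state_box:
  x1: [0.0, 1.0]
  x2: [0.0, 0.33]
  x3: [0.0, 45.0]
  x4: [0.0, 1.0]
reference:
  parameters: {p1: 5.0e-4, p2: 1.03e-1, p3: 2.36e-2, p4: 1.85e-2, p5: 2.5e-2}
  x0: {x1: 0.0, x2: 0.33, x3: 0.0, x4: 1.0}
  inputs: {u: 1.0}
  horizon: 314
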