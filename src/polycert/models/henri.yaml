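# Henri mechanism of enzyme catalysis: the enzyme-substrate complex is a
# dead-end species and the product is formed by a direct bimolecular step,
#   E + S <-> C  (p1, p2),   E + S -> E + P  (p3).
# Indistinguishable from Michaelis-Menten at steady state; the transient
# discriminates.  Enzyme eliminated by E + C = 1; P untracked.
# The reference parameterization used to generate synthetic data is part
# of this config (O(1) s^-1 rates on the 2 s observation window).
name: henri
species: [S, C, E]
parameters: [p1, p2, p3]
reactions:
  - name: binding
    reactants: {E: 1, S: 1}
    products: {C: 1}
    forward: p1
    reverse: p2
  - name: direct-catalysis
    reactants: {E: 1, S: 1}
    products: {E: 1}
    forward: p3
substitutions:
  E: {"1": 1.0, C: -1.0}
h: 0.1
param_box:
  p1: [0.0, 2.0]
  p2: [0.0, 2.0]
  p3: [0.0, 2.0]
state_box:
  S: [0.0, 1.0]
  C: [0.0, 1.0]
reference:
  parameters: {p1: 1.0, p2: 1.0, p3: 1.0}
  x0: {S: 0.999, C: 0.001}
  horizon: 20
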