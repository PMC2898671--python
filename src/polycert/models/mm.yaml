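# Michaelis-Menten mechanism of enzyme catalysis:
#   E + S <-> C  (binding p1, unbinding p2),  C -> E + P  (catalysis p3).
# The released product P is not tracked; the enzyme is eliminated by the
# conservation E + C = 1 (total enzyme fixed to 1), leaving the two-state
# system in substrate S and complex C.  Concentrations are normalized
# (dimensionless, order 1); time in seconds.
name: mm
species: [S, C, E]
parameters: [p1, p2, p3]
reactions:
  - name: binding
    reactants: {E: 1, S: 1}
    products: {C: 1}
    forward: p1
    reverse: p2
  - name: catalysis
    reactants: {C: 1}
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
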