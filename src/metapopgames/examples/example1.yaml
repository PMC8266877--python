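# Heterogeneous three-patch migration cycle with a unit-rate
# three-species cyclic (rock-paper-scissors) tournament in every patch.
# Patch equilibrium z* = (1/5, 2/5, 2/5); the coexistence equilibrium
# has x*_{i,1} = 1/15 and x*_{i,2} = x*_{i,3} = 2/15.
name: example1
tournament:
  matrix:
    - [0, 1, -1]
    - [-1, 0, 1]
    - [1, -1, 0]
dispersal:
  edges:   # from, to, rate_fwd, rate_rev
    - [1, 2, 0.5, 0.25]
    - [2, 3, 0.75, 0.75]
    - [3, 1, 0.25, 0.5]
simulation:
  t_end: 2000.0
  n_samples: 2001
  initial:
    kind: perturbed
    weight: 0.1
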