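# Homogeneous hub-and-spokes dispersal (patch 1 exchanges migrants with
# patches 2 and 3 at unit rates; no direct 2<->3 migration) with the same
# unit-rate three-species cyclic tournament.  z* is uniform, so the
# coexistence equilibrium is x*_{i,j} = 1/9 for all i, j.
name: example2
tournament:
  matrix:
    - [0, 1, -1]
    - [-1, 0, 1]
    - [1, -1, 0]
dispersal:
  edges:   # from, to, rate_fwd, rate_rev
    - [3, 1, 1.0, 1.0]
    - [1, 2, 1.0, 1.0]
simulation:
  t_end: 2000.0
  n_samples: 2001
  initial:
    kind: explicit
    proportions:
      - [0.24, 0.08, 0.10]
      - [0.05, 0.14, 0.12]
      - [0.04, 0.11, 0.12]
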