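# metapopgames

Coexistence and stability analysis of **tournament metapopulation
models**: `n` species in cyclic (rock–paper–scissors-like) competition
within each of `m` habitat patches, coupled by bidirectional migration
on a connected dispersal graph. The package is for theoretical
ecologists and dynamical-systems researchers who want to build such
models, decide whether they admit a stable coexistence equilibrium, and
simulate them.

## The model

Within a patch, pairwise dominance is coded in a skew-symmetric
tournament matrix `T` (`T_ij = k > 0` means species `i` displaces
species `j` at rate `k`), and the species proportions follow the
zero-sum replicator equation `dx_i/dt = x_i (Tx)_i`. Its interior fixed
point `y*` (with `T y* = 0`) is the completely mixed Nash equilibrium
of the matrix game; by Kaplansky's criterion it exists iff
`rank(T) = n − 1` and all cofactors of `T` are nonzero with one sign
(never for even `n`). In a single patch this equilibrium is only
neutrally stable: the relative entropy `V(x) = −Σ_i y*_i ln(x_i/y*_i)`
is a constant of motion and orbits cycle forever.

Migration is modelled like a reversible single-species mass-action
reaction network. With incidence matrix `B` and adjacency `A`, the
network is *detailed balanced* when a positive patch distribution `z*`
exists with `A_jk z*_j = A_kj z*_k` on every edge (equivalently,
`Ln K^eq ∈ Im(Bᵀ)`, or the Wegscheider cycle conditions). The edge
conductances `κ_p = A_jk z*_j` then give the migration flux of species
`i` as `−B 𝒦 Bᵀ (r_i / z*)`, where `r_i` is its patch profile.

A *balanced* metapopulation model couples the two:

    dx_ij/dt = x_ij (T Y* (p_j / y*))_i − (B 𝒦 Bᵀ (r_i / z*))_j

on the unit simplex of all `n·m` proportions. It has a unique interior
equilibrium, the product `x*_ij = y*_i z*_j`, and a clean stability
dichotomy driven by `V(x) = −Σ x*_ij ln(x_ij/x*_ij)`, whose orbital
derivative is never positive:

* **heterogeneous** models (`z*` non-uniform, `A` asymmetric):
  `x*` is asymptotically stable — migration damps the oscillations;
* **homogeneous** models (`z*` uniform, `A` symmetric): patches
  synchronize and the dynamics settle on a neutral limit cycle of the
  single-patch replicator flow around `x*`.

## Worked example

The packaged `example1` is a three-patch migration cycle (rates
`1↔2: 0.5/0.25`, `2↔3: 0.75/0.75`, `3↔1: 0.25/0.5`) with the unit-rate
three-species cyclic tournament in every patch:

```sh
$ metapopgames check src/metapopgames/examples/example1.yaml
tournament: n = 3, rank = 2, completely mixed: True
  y* = [0.333333 0.333333 0.333333]
dispersal: m = 3, edges = 3, detailed balanced: True (residual 3.33e-16)
  z* = [0.2 0.4 0.4]
  kappa = [0.1 0.3 0.1]
model class: balanced, heterogeneous
```

Every species settles at proportion `y*_i z*_j`: 1/15 ≈ 0.0667 in
patch 1 and 2/15 ≈ 0.1333 in patches 2 and 3 (`metapopgames
equilibrium …` prints the full table). Because `z*` is non-uniform the
model is heterogeneous, so this equilibrium is asymptotically stable —
`metapopgames simulate …` integrates the system, writes tidy
trajectory/Lyapunov CSVs, and reports

```
long-run classification: converged (persistence assumed)
```

with the final distance to `x*` around 1e-13 at `t = 2000`. The
homogeneous `example2` (hub-and-spokes graph, unit rates) instead
reports `limit_cycle_synchronized`: the three patches synchronize to
machine precision while the oscillation stays a distance ≈ 0.03 from
`x* = 1/9` and `V` plateaus at a positive value.

The same can be done from Python:

```python
import metapopgames as mg

model = mg.load_example("example1").assemble()
x0 = mg.perturbed_initial_state(model.x_star, weight=0.1)
traj = mg.simulate(model, x0, t_end=2000.0)
print(mg.classify_longrun(model, traj).label)   # "converged"
```

`metapopgames generate --n 5 --m 4 --extra-edges 2 --seed 3 --out m.yaml`
emits a random model config that is balanced by construction (the
generator draws `z*` and `κ` first and solves for the rate constants).

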