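# Methods

## Model class

The package analyzes metapopulation models in which the same `n`
species compete within each of `m` spatially homogeneous patches and
migrate between patches. Three structural assumptions define the class
(models outside it are rejected at assembly time, with a diagnostic
certificate):

1. **Complete tournament competition.** Every pair of species competes,
   with one dominant (`i + j → 2i` at rate `k_ij`); the interaction
   matrix `T` is skew-symmetric with no zero off-diagonal entry. Ties
   (`T_ij = 0` for `i ≠ j`) are rejected rather than modelled as draws.
2. **Completely mixed game.** The zero-sum game with payoff `T` has a
   unique interior optimal strategy `y*`. Kaplansky's criterion
   (`rank(T) = n − 1`, all cofactors nonzero with a common sign) is the
   decision procedure; an even number of species never qualifies.
3. **Detailed-balanced dispersal.** Migration is bidirectional on a
   connected graph and admits a positive patch distribution `z*` with
   zero net flux on every edge.

Under 1–3 the coupled system on the `mn`-simplex has the unique
interior equilibrium `x*_ij = y*_i z*_j`, and the relative entropy
`V(x) = −Σ x*_ij ln(x_ij / x*_ij)` has nonpositive orbital derivative
`dV/dt = Σ_i y*_i (z*/r_i)ᵀ B 𝒦 Bᵀ (r_i/z*)`, vanishing exactly when
every species' patch profile `r_i` is proportional to `z*`. LaSalle's
invariance principle then gives the dichotomy implemented by the
long-run classifier: convergence to `x*` for heterogeneous models;
patch synchronization onto a neutral replicator limit cycle for
homogeneous ones. On the synchronized manifold the species totals obey
`dq_i/dt = (1/m) q_i (Tq)_i` — the single-patch replicator flow slowed
by the factor `m` — which is what the reduction test checks.

**Persistence is assumed, not verified.** The global version of the
stability statements requires that interior trajectories stay away from
the simplex boundary; the package does not test this, and every
classification result carries a `persistence_assumed` flag. The
classifier therefore reports observed local behavior of the simulated
trajectory, nothing stronger.

## Numerical choices

* **Interior Nash equilibrium.** Null space of `T` by SVD with relative
  rank threshold `1e-9 · σ_max`; a one-dimensional, strictly one-signed
  null vector is normalized to `y*`. Degenerate cases fall back to the
  maximin linear program (HiGHS), which doubles as the independent
  oracle in the tests. Closed forms for `n = 3` and `n = 5` (the
  normalized sub-Pfaffian expressions) are provided and cross-checked
  against both routes.
* **Kaplansky certificate in exact arithmetic.** Cofactor signs are
  brittle in floating point, so rank and the full cofactor matrix are
  computed exactly: binary floats are dyadic rationals, `Fraction`
  conversion is lossless, and sympy's rational adjugate yields exact
  signs for the matrix as stored. There is deliberately no inexact
  fallback path. The certificate exposes the raw cofactors so callers
  can inspect near-degenerate cases (e.g. cofactors that would vanish
  under a slightly different rounding) instead of the package guessing
  intent.
* **Detailed-balance test.** Two independent criteria are always
  computed and must agree: the least-squares residual of `Ln K^eq`
  against `Im(Bᵀ)` (basis-free, max-norm, default tolerance `1e-9`) and
  the log-form Wegscheider sums over a fundamental cycle basis built
  from a BFS spanning tree. Near-balanced graphs are reported
  unbalanced with the residual attached; nothing is projected onto the
  balanced manifold, since the theory is exact-balance only.
* **Thermodynamic equilibrium `z*`.** Log-space propagation of the edge
  ratios along the BFS spanning tree rooted at patch 1, then
  normalization; non-tree edges serve as consistency checks. The result
  is scale-invariant in the rates and independent of edge order.
* **Edge orientation conventions.** The direction listed first in an
  edge record is "forward"; the incidence column carries −1 at the
  origin. Files and CLI output are 1-based; in-memory arrays 0-based.
* **Integration.** `solve_ivp` with DOP853, `rtol 1e-10`, `atol 1e-12`,
  dense sampling on a uniform grid. No simplex re-projection is applied:
  conservation of the grand total (observed drift ~1e-15 over
  `t = 1000`) and monotonicity of `V` are diagnostics of integrator
  quality, and enforcing them would mask error. Boundary states raise
  in `V` and its rate (the entropy is defined on the open simplex);
  nothing is clamped.
* **Long-run classification.** `converged` means
  `‖x(t_end) − x*‖∞ < 1e-6`. `limit_cycle_synchronized` requires
  cross-patch spread below `1e-6`, distance to `x*` above `1e-2`
  throughout the trailing 10% of the horizon, and a positive `V`
  plateau with relative variation below `1e-8` over that window. The
  plateau tolerance is set one order above the measured integrator-
  induced `V` drift on an analytically `V`-constant synchronized cycle
  (~2.5e-9 relative at the default tolerances over a `t = 2000`
  horizon), so that genuine plateaus are not misread as transients
  while any real decay — orders of magnitude larger until
  synchronization completes — still fails the check. Everything else is
  `undetermined`.
* **Default perturbed start.** `x0 = (1 − w)·x* + w·u` with `w = 0.1`
  and `u` the simplex barycenter when no seed is given (fully
  deterministic), or a Dirichlet(1) draw under a seed. Note the
  barycenter blend of the worked cyclic-tournament models is
  species-uniform within every patch and therefore relaxes by pure
  dispersal, quickly; seeded random starts also excite the weakly
  damped oscillatory modes and show the slower spiral approach to
  `x*`.

## Synthetic generators

The generators exist so that every operation and invariant can be
fuzz-tested without external data; their defaults are the study
conditions of the worked three-species / three-patch models and are not
tuning knobs.

* **Tournaments** (`n` odd): a random Hamiltonian dominance cycle plus
  random orientation of the remaining pairs, rates uniform in
  `[0.5, 2.0]` (order-one rates, as in the worked examples), rejection
  sampled against the Kaplansky certificate. The cyclic backbone keeps
  acceptance high for `n ≤ 9`, where uniformly random orientations
  often fail to be completely mixed.
* **Dispersal graphs**: a uniform random labeled spanning tree (Prüfer
  sequence) plus a chosen number of random chords; `z*` uniform when a
  homogeneous model is requested (which forces a symmetric adjacency),
  otherwise Dirichlet(α = 5) — interior, away from the boundary;
  per-edge `κ` uniform in `[0.1, 0.5]`, the range of the worked cyclic
  example. Rates are recovered as `A_jk = κ_p / z*_j`, so the graph is
  detailed balanced **by construction** and the drawn `z*`, `κ` must be
  recovered exactly by the analysis path (round-trip tests, `1e-10`).
* All randomness flows through a single `numpy.random.Generator`
  threaded explicitly through the draws; no global state.

What the generated data do *not* emulate: demographic stochasticity,
spatially explicit (lattice/PDE) structure, per-patch differences in
the tournament, non-reversible or time-varying migration, and
non-detailed-balanced networks except as explicit negative controls.
Passing tests therefore say nothing about those regimes; they validate
the deterministic, well-mixed, detailed-balanced class above.

## Problem sizes and horizons

Worked-model simulations use `t_end = 2000` with 2001 stored samples,
long enough for the heterogeneous example to reach the `1e-6`
convergence tolerance and for the homogeneous example to synchronize to
machine precision. Property sweeps run 100 random balanced models to
`t = 200` (grand-total drift bound `1e-8`; measured drift is ~1e-15
even at `t = 1000`, which a smaller three-model check exercises),
1000 random graphs for the balance-test agreement sweep, and 1000
random (graph, weight) pairs for the nonnegativity of the migration
quadratic form.

## Known limitations

* Persistence (no boundary extinction from interior starts) is an
  assumption throughout; models that lose species numerically would be
  flagged only indirectly (boundary states raise in `V`).
* The classifier needs a long enough horizon; it answers
  `undetermined` rather than extrapolating from a transient.
* Exact cofactor computation costs grow quickly with `n` (dense
  rational adjugate); intended for the small species counts (`n ≤ 9`)
  this class of models targets.
* Heterogeneous-model convergence can be slow when the start excites
  the weakly damped oscillatory modes; the `1e-6` convergence tolerance
  at a given horizon is a property of (model, start, horizon), not of
  the model alone.
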