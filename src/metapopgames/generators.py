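"""Random valid tournaments and detailed-balanced dispersal graphs.

Every operation in the package is fuzz-testable without external data:
tournaments are drawn by orienting a random Hamiltonian dominance cycle
plus random orientations of the remaining pairs (rejection-sampled
against Kaplansky's criterion, which keeps rejection rates low for odd
``n <= 9``), and dispersal graphs are built detailed-balanced *by
construction* — the patch equilibrium ``z*`` and edge conductances
``kappa`` are drawn first and the rate constants recovered from
``A[j, k] = kappa_p / z*_j``, ``A[k, j] = kappa_p / z*_k``.

All randomness flows through one explicit ``numpy.random.Generator``
derived from a single integer seed; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import networkx as nx
import numpy as np

from .dispersal import DispersalGraph, build_graph
from .models import BalancedModel, assemble
from .tournaments import TournamentMatrix, is_completely_mixed, validate_tournament

__all__ = [
    "GeneratorSpec",
    "GeneratedGraph",
    "random_tournament",
    "random_balanced_graph",
    "random_model",
    "perturbed_initial_state",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic generator.

    Defaults mirror the worked three-species / three-patch setting:
    dominance rates of order one (uniform in [0.5, 2.0]), edge
    conductances in the [0.1, 0.5] range of the worked cyclic example,
    and an interior patch equilibrium drawn from a Dirichlet(5)
    distribution so that no patch weight collapses toward zero.
    ``n`` must be odd whenever a coexistence equilibrium is required
    (even-order tournaments are never completely mixed).
    """

    n: int = 3
    m: int = 3
    extra_edges: int = 1
    tournament_rate_range: tuple[float, float] = (0.5, 2.0)
    kappa_range: tuple[float, float] = (0.1, 0.5)
    dirichlet_alpha: float = 5.0
    homogeneous: bool = False
    seed: int = 0


class GeneratedGraph(NamedTuple):
    """A generated graph together with the equilibrium data it was built from."""

    graph: DispersalGraph
    z_star: np.ndarray
    kappas: np.ndarray


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_tournament(n: int, rng=0, rate_range: tuple[float, float] = (0.5, 2.0),
                      max_attempts: int = 1000) -> TournamentMatrix:
    """Draw a complete tournament with a completely mixed equilibrium.

    A random Hamiltonian cycle of dominance guarantees cyclic structure;
    remaining pairs are oriented uniformly at random and all rates drawn
    uniformly from ``rate_range``.  Candidates are rejected until
    Kaplansky's criterion holds.

    Raises
    ------
    ValueError
        If ``n`` is even (no completely mixed equilibrium can exist) or
        the rejection budget is exhausted.
    """
    if n < 3 or n % 2 == 0:
        raise ValueError(
            f"a completely mixed tournament requires odd n >= 3, got n = {n}"
        )
    rng = _as_rng(rng)
    lo, hi = rate_range
    for attempt in range(1, max_attempts + 1):
        T = np.zeros((n, n))
        order = rng.permutation(n)
        on_cycle = set()
        for a in range(n):
            i, j = order[a], order[(a + 1) % n]
            rate = rng.uniform(lo, hi)
            T[i, j] = rate
            T[j, i] = -rate
            on_cycle.add(frozenset((int(i), int(j))))
        for i, j in combinations(range(n), 2):
            if frozenset((i, j)) in on_cycle:
                continue
            rate = rng.uniform(lo, hi)
            if rng.random() < 0.5:
                i, j = j, i
            T[i, j] = rate
            T[j, i] = -rate
        candidate = validate_tournament(T)
        if is_completely_mixed(candidate).completely_mixed:
            return candidate
    raise ValueError(
        f"no completely mixed tournament found in {max_attempts} attempts (n = {n})"
    )


def random_balanced_graph(m: int, rng=0, extra_edges: int = 0,
                          kappa_range: tuple[float, float] = (0.1, 0.5),
                          dirichlet_alpha: float = 5.0,
                          homogeneous: bool = False) -> GeneratedGraph:
    """Draw a connected dispersal graph that is detailed balanced by construction.

    A uniform random labeled spanning tree plus ``extra_edges`` random
    chords fixes the topology; ``z*`` (uniform if ``homogeneous``, else
    Dirichlet) and per-edge ``kappa`` are drawn, and the rate constants
    set to ``A[j, k] = kappa_p / z*_j``.  A homogeneous draw therefore
    yields a symmetric adjacency matrix.
    """
    if m < 2:
        raise ValueError(f"need at least 2 patches, got m = {m}")
    max_extra = m * (m - 1) // 2 - (m - 1)
    if not 0 <= extra_edges <= max_extra:
        raise ValueError(
            f"extra_edges must be in [0, {max_extra}] for m = {m}, got {extra_edges}"
        )
    rng = _as_rng(rng)
    # uniform random labeled tree via a Pruefer sequence
    if m == 2:
        tree_edges = [(0, 1)]
    else:
        prufer = [int(rng.integers(0, m)) for _ in range(m - 2)]
        tree_edges = list(nx.from_prufer_sequence(prufer).edges())
    edges = [tuple(sorted(e)) for e in tree_edges]
    present = set(edges)
    candidates = [e for e in combinations(range(m), 2) if e not in present]
    if extra_edges:
        pick = rng.choice(len(candidates), size=extra_edges, replace=False)
        edges += [candidates[int(i)] for i in np.sort(pick)]
    if homogeneous:
        z = np.full(m, 1.0 / m)
    else:
        z = rng.dirichlet(np.full(m, dirichlet_alpha))
    kappas = rng.uniform(*kappa_range, size=len(edges))
    records = []
    for (j, k), kp in zip(edges, kappas):
        records.append((j + 1, k + 1, kp / z[j], kp / z[k]))
    return GeneratedGraph(graph=build_graph(records, m=m), z_star=z, kappas=kappas)


def random_model(spec: GeneratorSpec = GeneratorSpec()) -> BalancedModel:
    """Assemble a random balanced model under the given study conditions."""
    rng = _as_rng(spec.seed)
    T = random_tournament(spec.n, rng, rate_range=spec.tournament_rate_range)
    gen = random_balanced_graph(spec.m, rng, extra_edges=spec.extra_edges,
                                kappa_range=spec.kappa_range,
                                dirichlet_alpha=spec.dirichlet_alpha,
                                homogeneous=spec.homogeneous)
    return assemble(T, gen.graph)


def perturbed_initial_state(x_star, weight: float = 0.1, seed=None) -> np.ndarray:
    """Convex combination of the equilibrium with an interior point.

    ``x0 = (1 - weight) * x* + weight * u`` where ``u`` is the uniform
    barycenter of the simplex when ``seed`` is None (deterministic
    default) or a Dirichlet(1) draw otherwise.  Strictly interior for
    any ``weight`` in (0, 1].
    """
    xs = np.asarray(x_star, dtype=float)
    if not 0 < weight <= 1:
        raise ValueError(f"weight must be in (0, 1], got {weight}")
    if seed is None:
        u = np.full(xs.shape, 1.0 / xs.size)
    else:
        rng = _as_rng(seed)
        u = rng.dirichlet(np.ones(xs.size)).reshape(xs.shape)
    return (1.0 - weight) * xs + weight * u
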