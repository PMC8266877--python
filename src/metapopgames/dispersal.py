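"""Inter-patch migration: dispersal graphs and detailed balance.

Migration among ``m`` habitat patches is modelled exactly like a
reversible single-species mass-action reaction network: each edge
``j <-> k`` of a connected dispersal graph carries a forward rate
constant ``A[j, k]`` and a reverse rate constant ``A[k, j]`` (both
strictly positive).  With incidence matrix ``B`` (one column per edge,
-1 at the origin, +1 at the destination) and Laplacian
``L = Delta - A.T`` (``Delta`` the diagonal of out-degrees), the net
migration flux of one species with patch profile ``r`` is ``-L r``.

The network is *detailed balanced* when a strictly positive patch
distribution ``z*`` exists at which every individual edge flux
vanishes: ``A[j, k] z*_j = A[k, j] z*_k``.  Equivalently the log
equilibrium constants ``ln(A[j, k] / A[k, j])`` lie in the row space of
``B`` (image test), or every cycle satisfies the Wegscheider product
identity.  On a balanced graph the edge conductances
``kappa_p = A[j, k] z*_j`` give the compact form
``L = B diag(kappa) B.T diag(z*)^{-1}``, so the migration flux is also
``-B diag(kappa) B.T (r / z*)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "DispersalGraph",
    "BalanceCertificate",
    "DispersalError",
    "NotDetailedBalancedError",
    "build_graph",
    "read_edge_list",
    "incidence_and_laplacian",
    "check_detailed_balance",
    "thermodynamic_equilibrium",
    "edge_kappas",
    "migration_rhs",
    "classify_homogeneity",
]


class DispersalError(ValueError):
    """Raised when an edge list does not define a valid dispersal graph."""


class NotDetailedBalancedError(ValueError):
    """Raised when an operation requires detailed balance and the graph lacks it."""

    def __init__(self, message, certificate=None):
        super().__init__(message)
        self.certificate = certificate


@dataclass(frozen=True)
class DispersalGraph:
    """A validated bidirectional dispersal graph on ``m`` patches.

    Edges keep their input order and orientation: edge ``p`` runs from
    ``origins[p]`` to ``destinations[p]`` (0-based internally; file and
    CLI interfaces are 1-based) with forward rate ``forward[p]`` and
    reverse rate ``reverse[p]``.
    """

    m: int
    origins: np.ndarray      # (r,) int
    destinations: np.ndarray  # (r,) int
    forward: np.ndarray       # (r,) float, rate origin -> destination
    reverse: np.ndarray       # (r,) float, rate destination -> origin

    def __post_init__(self):
        for name in ("origins", "destinations"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        for name in ("forward", "reverse"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("origins", "destinations", "forward", "reverse"):
            getattr(self, name).setflags(write=False)

    @property
    def r(self) -> int:
        """Number of (bidirectional) edges."""
        return len(self.origins)

    @property
    def adjacency(self) -> np.ndarray:
        """Weighted adjacency: ``A[j, k]`` is the migration rate j -> k."""
        A = np.zeros((self.m, self.m))
        A[self.origins, self.destinations] = self.forward
        A[self.destinations, self.origins] = self.reverse
        return A

    @property
    def degrees(self) -> np.ndarray:
        """Total outgoing rate ``delta_j = sum_k A[j, k]`` per patch."""
        return self.adjacency.sum(axis=1)

    @property
    def incidence(self) -> np.ndarray:
        """Incidence matrix ``B``: column p has -1 at the origin, +1 at the destination."""
        B = np.zeros((self.m, self.r))
        B[self.origins, np.arange(self.r)] = -1.0
        B[self.destinations, np.arange(self.r)] = 1.0
        return B

    @property
    def laplacian(self) -> np.ndarray:
        """Out-degree Laplacian ``L = Delta - A.T``; satisfies ``1.T L = 0``."""
        A = self.adjacency
        return np.diag(A.sum(axis=1)) - A.T

    @property
    def keq(self) -> np.ndarray:
        """Per-edge equilibrium constants ``K_p = forward_p / reverse_p``."""
        return self.forward / self.reverse

    def support(self) -> nx.Graph:
        """Undirected support graph (networkx), nodes ``0..m-1``."""
        g = nx.Graph()
        g.add_nodes_from(range(self.m))
        g.add_edges_from(zip(self.origins, self.destinations))
        return g


@dataclass(frozen=True)
class BalanceCertificate:
    """Verdict and evidence of the detailed-balance test.

    ``residual`` is the max-norm distance of ``ln K_eq`` from the row
    space of the incidence matrix; ``cycle_residuals`` are the log-form
    Wegscheider sums over a fundamental cycle basis (empty for trees).
    ``z_star`` and ``kappas`` are present only when balanced.
    """

    balanced: bool
    residual: float
    cycle_residuals: np.ndarray
    keq: np.ndarray
    z_star: np.ndarray | None = None
    kappas: np.ndarray | None = None


def build_graph(edge_list, m: int | None = None, tol: float = 0.0) -> DispersalGraph:
    """Validate an edge list ``(from, to, rate_fwd, rate_rev)`` (1-based patches).

    Raises
    ------
    DispersalError
        On self-loops, nonpositive/unidirectional rates, duplicate
        edges, or a disconnected support graph.
    """
    records = [(int(j), int(k), float(f), float(rv)) for j, k, f, rv in edge_list]
    if not records:
        raise DispersalError("edge list is empty")
    if m is None:
        m = max(max(j, k) for j, k, _, _ in records)
    seen = set()
    for j, k, f, rv in records:
        if not (1 <= j <= m and 1 <= k <= m):
            raise DispersalError(f"patch index out of range in edge ({j}, {k})")
        if j == k:
            raise DispersalError(f"self-loop on patch {j}")
        if f <= tol or rv <= tol:
            raise DispersalError(
                f"migration {j} <-> {k} must be bidirectional with positive rates "
                f"(got forward {f}, reverse {rv})"
            )
        key = frozenset((j, k))
        if key in seen:
            raise DispersalError(f"duplicate edge between patches {j} and {k}")
        seen.add(key)
    origins = np.array([j - 1 for j, _, _, _ in records])
    dests = np.array([k - 1 for _, k, _, _ in records])
    fwd = np.array([f for _, _, f, _ in records])
    rev = np.array([rv for _, _, _, rv in records])
    G = DispersalGraph(m=m, origins=origins, destinations=dests, forward=fwd, reverse=rev)
    if not nx.is_connected(G.support()):
        raise DispersalError("dispersal graph support must be connected")
    return G


def read_edge_list(path) -> DispersalGraph:
    """Read a whitespace-delimited edge-list file: ``from to rate_fwd rate_rev``.

    Patch indices are 1-based; ``#`` starts a comment.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise DispersalError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            records.append(tuple(parts))
    return build_graph(records)


def incidence_and_laplacian(G: DispersalGraph) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(B, L)``; columns of B sum to 0, rank(B) = m - 1, 1.T L = 0."""
    return G.incidence, G.laplacian


def _fundamental_cycles(G: DispersalGraph) -> list[np.ndarray]:
    """Edge-space cycle basis: one signed vector w per non-tree edge, B w = 0."""
    support = G.support()
    tree = nx.bfs_tree(support, 0)
    tree_edges = {frozenset(e) for e in tree.edges()}
    edge_index = {}
    for p in range(G.r):
        edge_index[frozenset((G.origins[p], G.destinations[p]))] = p
    cycles = []
    for p in range(G.r):
        key = frozenset((G.origins[p], G.destinations[p]))
        if key in tree_edges:
            continue
        # path through the tree from destination back to origin closes the cycle
        path = nx.shortest_path(tree.to_undirected(as_view=True),
                                G.destinations[p], G.origins[p])
        w = np.zeros(G.r)
        w[p] = 1.0
        for u, v in zip(path[:-1], path[1:]):
            q = edge_index[frozenset((u, v))]
            w[q] = 1.0 if (G.origins[q] == u and G.destinations[q] == v) else -1.0
        cycles.append(w)
    return cycles


def check_detailed_balance(G: DispersalGraph, tol: float = 1e-9) -> BalanceCertificate:
    """Detailed-balance test via the image criterion and Wegscheider cycles.

    The graph is balanced iff ``ln K_eq`` lies in the row space of the
    incidence matrix (residual of the least-squares projection below
    ``tol``), equivalently iff every fundamental cycle's signed sum of
    log equilibrium constants vanishes.  Both tests are computed and
    must agree; trees are always balanced.  Near misses (residual in
    ``[tol, 10 tol)``) are reported unbalanced with the residual
    attached, never projected onto the balanced manifold.
    """
    lnK = np.log(G.keq)
    Bt = G.incidence.T
    sol, *_ = np.linalg.lstsq(Bt, lnK, rcond=None)
    residual = float(np.abs(lnK - Bt @ sol).max())
    cycles = _fundamental_cycles(G)
    cyc_res = np.array([abs(float(w @ lnK)) for w in cycles])
    image_ok = residual < tol
    wegscheider_ok = bool(np.all(cyc_res < tol)) if len(cyc_res) else True
    if image_ok != wegscheider_ok:  # pragma: no cover - mathematically equivalent
        raise RuntimeError(
            "image test and Wegscheider cycle test disagree "
            f"(residual {residual:.3g}, cycles {cyc_res})"
        )
    if not image_ok:
        return BalanceCertificate(balanced=False, residual=residual,
                                  cycle_residuals=cyc_res, keq=G.keq)
    z = _propagate_equilibrium(G)
    kappas = G.forward * z[G.origins]
    return BalanceCertificate(balanced=True, residual=residual,
                              cycle_residuals=cyc_res, keq=G.keq,
                              z_star=z, kappas=kappas)


def _propagate_equilibrium(G: DispersalGraph) -> np.ndarray:
    """Propagate K_eq ratios along a BFS spanning tree from patch 1; normalize."""
    edge_index = {}
    for p in range(G.r):
        edge_index[frozenset((G.origins[p], G.destinations[p]))] = p
    support = G.support()
    logz = np.full(G.m, np.nan)
    logz[0] = 0.0
    for u, v in nx.bfs_edges(support, 0):
        p = edge_index[frozenset((u, v))]
        step = np.log(G.keq[p])  # log(z_dest / z_origin)
        if G.origins[p] == u:
            logz[v] = logz[u] + step
        else:
            logz[v] = logz[u] - step
    z = np.exp(logz - logz.max())
    return z / z.sum()


def thermodynamic_equilibrium(G: DispersalGraph, tol: float = 1e-9) -> np.ndarray:
    """Strictly positive simplex vector ``z*`` with zero flux on every edge.

    Computed by spanning-tree propagation of the per-edge ratios
    ``z_k / z_j = A[j, k] / A[k, j]``; non-tree edges are consistency
    checks.  Raises if the graph is not detailed balanced.
    """
    cert = check_detailed_balance(G, tol=tol)
    if not cert.balanced:
        raise NotDetailedBalancedError(
            f"graph is not detailed balanced (residual {cert.residual:.3g})",
            certificate=cert,
        )
    return cert.z_star


def edge_kappas(G: DispersalGraph, z_star, tol: float = 1e-9) -> np.ndarray:
    """Edge conductances ``kappa_p = A[j, k] z*_j = A[k, j] z*_k``.

    Both defining products must agree within ``tol`` (relative), which
    verifies that ``z_star`` is a thermodynamic equilibrium of ``G``.
    """
    z = np.asarray(z_star, dtype=float)
    kf = G.forward * z[G.origins]
    kr = G.reverse * z[G.destinations]
    scale = np.maximum(np.abs(kf), 1.0)
    if np.any(np.abs(kf - kr) > tol * scale):
        raise NotDetailedBalancedError(
            "z_star is not a thermodynamic equilibrium of this graph "
            f"(max edge flux {np.abs(kf - kr).max():.3g})"
        )
    return kf


def migration_rhs(G: DispersalGraph, r_i, certificate: BalanceCertificate | None = None
                  ) -> np.ndarray:
    """Net migration flux ``Psi_i`` for one species' patch profile ``r_i``.

    Without a certificate this is the Laplacian form ``-L r_i`` (valid
    for any graph).  With a balanced certificate the compact form
    ``-B diag(kappa) B.T (r_i / z*)`` is used; the two agree on balanced
    graphs.  Components always sum to zero.
    """
    r = np.asarray(r_i, dtype=float)
    if r.shape != (G.m,):
        raise ValueError(f"patch profile has shape {r.shape}, expected ({G.m},)")
    if certificate is None:
        return -G.laplacian @ r
    if not certificate.balanced:
        raise NotDetailedBalancedError("certificate reports an unbalanced graph",
                                       certificate=certificate)
    B = G.incidence
    return -B @ (certificate.kappas * (B.T @ (r / certificate.z_star)))


def classify_homogeneity(certificate: BalanceCertificate, tol: float = 1e-9) -> str:
    """``"homogeneous"`` iff ``z*`` is uniform (equivalently A symmetric)."""
    if not certificate.balanced:
        raise NotDetailedBalancedError("homogeneity is defined for balanced models only",
                                       certificate=certificate)
    z = certificate.z_star
    m = len(z)
    return "homogeneous" if np.abs(z - 1.0 / m).max() < tol else "heterogeneous"
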