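"""Intra-patch competition: tournament matrices and replicator dynamics.

Pairwise dominance among ``n`` species is coded in a skew-symmetric
*tournament matrix* ``T``: ``T[i, j] = k > 0`` means species ``i``
displaces species ``j`` at rate ``k``, and ``T[j, i] = -k``.  Within a
single well-mixed patch the species proportions ``x`` then follow the
zero-sum replicator equation

    dx_i/dt = x_i * (T x)_i ,

whose interior fixed point (the *coexistence equilibrium*) coincides
with the completely mixed Nash equilibrium of the symmetric zero-sum
game with payoff matrix ``T``.  Kaplansky's criterion decides whether
such an equilibrium exists: ``T`` must have rank ``n - 1`` and all of
its cofactors must be nonzero and share a sign.  The relative-entropy
function ``V(x) = -sum_i y*_i log(x_i / y*_i)`` is a constant of motion
of the replicator flow, so interior orbits are closed curves around the
equilibrium (neutral stability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy
from scipy.integrate import solve_ivp
from scipy.optimize import linprog

__all__ = [
    "TournamentMatrix",
    "KaplanskyCertificate",
    "NashResult",
    "MeanFieldTrajectory",
    "validate_tournament",
    "tournament_from_edges",
    "replicator_rhs",
    "is_completely_mixed",
    "nash_equilibrium",
    "lp_equilibrium",
    "ne_closed_form_3",
    "ne_closed_form_5",
    "meanfield_lyapunov",
    "simulate_meanfield",
]


class TournamentError(ValueError):
    """Raised when a matrix is not a valid tournament."""


@dataclass(frozen=True)
class TournamentMatrix:
    """A validated complete tournament on ``n`` species.

    Attributes
    ----------
    n : int
        Number of species.
    rates : (n, n) ndarray
        Skew-symmetric matrix of pairwise dominance rates, zero diagonal,
        no zero off-diagonal entry.
    """

    n: int
    rates: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        self.rates.setflags(write=False)


@dataclass(frozen=True)
class KaplanskyCertificate:
    """Rank/cofactor evidence for (non-)existence of an interior equilibrium.

    ``rank`` and ``cofactors`` are computed in exact rational arithmetic
    (binary floats are dyadic rationals, so the signs are exact for the
    matrix as given).  ``sign`` is +1 or -1 when all n^2 cofactors share
    that sign, 0 otherwise.
    """

    rank: int
    n: int
    sign: int
    cofactors: np.ndarray
    completely_mixed: bool


@dataclass(frozen=True)
class NashResult:
    """Outcome of the Nash-equilibrium computation for a tournament game."""

    strategy: np.ndarray | None
    completely_mixed: bool
    certificate: KaplanskyCertificate
    residual: float = np.nan
    method: str = ""


@dataclass
class MeanFieldTrajectory:
    """Sampled solution of the single-patch replicator equation."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), n)
    lyapunov_values: np.ndarray | None = None


def validate_tournament(matrix, tol: float = 1e-12) -> TournamentMatrix:
    """Validate a square matrix as a complete tournament.

    Checks zero diagonal, skew-symmetry (``|T + T.T| <= tol``) and
    completeness (every off-diagonal entry nonzero).  The returned
    matrix is exactly skew-symmetrized via ``(T - T.T) / 2``.

    Raises
    ------
    TournamentError
        If the matrix is not square, not skew-symmetric within ``tol``,
        has a nonzero diagonal, or any pair of species does not compete.
    """
    T = np.asarray(matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise TournamentError(f"tournament matrix must be square, got shape {T.shape}")
    n = T.shape[0]
    if np.any(np.abs(np.diag(T)) > tol):
        raise TournamentError("tournament matrix must have zero diagonal")
    asym = np.abs(T + T.T).max()
    if asym > tol:
        raise TournamentError(
            f"matrix is not skew-symmetric: max |T_ij + T_ji| = {asym:.3g} > tol"
        )
    off = T[~np.eye(n, dtype=bool)]
    if n > 1 and np.any(off == 0.0):
        raise TournamentError(
            "incomplete tournament: some pair of species has a zero dominance rate"
        )
    T = (T - T.T) / 2.0
    np.fill_diagonal(T, 0.0)
    return TournamentMatrix(n=n, rates=T)


def tournament_from_edges(edges, n: int | None = None, tol: float = 1e-12) -> TournamentMatrix:
    """Build a tournament from ``(winner, loser, rate)`` records (1-based).

    Every unordered species pair must appear exactly once with a
    strictly positive rate.
    """
    edges = list(edges)
    if n is None:
        n = max(max(int(w), int(l)) for w, l, _ in edges)
    T = np.zeros((n, n))
    seen = set()
    for w, l, rate in edges:
        w, l, rate = int(w), int(l), float(rate)
        if not (1 <= w <= n and 1 <= l <= n) or w == l:
            raise TournamentError(f"invalid species pair ({w}, {l})")
        if rate <= 0:
            raise TournamentError(f"dominance rate must be positive, got {rate}")
        key = frozenset((w, l))
        if key in seen:
            raise TournamentError(f"duplicate competition record for pair ({w}, {l})")
        seen.add(key)
        T[w - 1, l - 1] = rate
        T[l - 1, w - 1] = -rate
    return validate_tournament(T, tol=tol)


def replicator_rhs(T: TournamentMatrix, x) -> np.ndarray:
    """Right-hand side ``x_i (T x)_i`` of the replicator equation.

    The components always sum to zero (the flow is tangent to the
    simplex), because ``x . T x = 0`` for skew-symmetric ``T``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (T.n,):
        raise ValueError(f"state has shape {x.shape}, expected ({T.n},)")
    return x * (T.rates @ x)


def _exact_matrix(T: TournamentMatrix) -> sympy.Matrix:
    # Fraction(float) is exact, so rank and cofactor signs are those of
    # the matrix actually stored, not of a rounded version.
    n = T.n
    return sympy.Matrix(
        n, n, [sympy.Rational(Fraction(T.rates[i, j])) for i in range(n) for j in range(n)]
    )


def is_completely_mixed(T: TournamentMatrix, tol: float = 1e-12) -> KaplanskyCertificate:
    """Kaplansky's criterion for a completely mixed tournament game.

    True iff ``rank(T) = n - 1`` and all ``n**2`` cofactors are nonzero
    with a common sign.  Rank and cofactors are evaluated in exact
    rational arithmetic; ``tol`` is unused on that path and kept for
    interface stability.
    """
    n = T.n
    M = _exact_matrix(T)
    rank = M.rank()
    if n == 1:
        cof = np.ones((1, 1))
        return KaplanskyCertificate(rank=rank, n=n, sign=1, cofactors=cof,
                                    completely_mixed=True)
    # adjugate(M)[j, i] is the (i, j) cofactor; exact for rational entries
    adj = M.adjugate()
    cof_exact = [[adj[j, i] for j in range(n)] for i in range(n)]
    signs = {int(sympy.sign(cof_exact[i][j])) for i in range(n) for j in range(n)}
    if signs == {1}:
        sign = 1
    elif signs == {-1}:
        sign = -1
    else:
        sign = 0
    cof = np.array([[float(c) for c in row] for row in cof_exact])
    cm = (rank == n - 1) and sign != 0
    return KaplanskyCertificate(rank=rank, n=n, sign=sign, cofactors=cof,
                                completely_mixed=cm)


def lp_equilibrium(T: TournamentMatrix) -> tuple[np.ndarray, float]:
    """Maximin strategy of the zero-sum game via linear programming.

    Maximizes ``v`` subject to ``(T x)_j + v <= 0`` for all ``j``,
    ``sum(x) = 1``, ``x >= 0``.  For skew-symmetric payoffs the game
    value is 0 and any optimizer is a Nash equilibrium; when the game is
    completely mixed the optimizer is unique and interior.  Used as the
    independent cross-check of the null-space solver.
    """
    n = T.n
    # variables: (x_1..x_n, v); maximize v
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_ub = np.hstack([T.rates, np.ones((n, 1))])
    b_ub = np.zeros(n)
    A_eq = np.zeros((1, n + 1))
    A_eq[0, :n] = 1.0
    b_eq = np.array([1.0])
    bounds = [(0, None)] * n + [(None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - LP on this polytope is always feasible
        raise RuntimeError(f"game LP failed: {res.message}")
    return res.x[:n], res.x[-1]


def nash_equilibrium(T: TournamentMatrix, tol: float = 1e-9) -> NashResult:
    """Completely mixed Nash equilibrium of the tournament game, if any.

    The null space of ``T`` is computed by SVD with relative rank
    threshold ``1e-9 * sigma_max``.  A one-dimensional, strictly
    one-signed null vector normalizes to the unique interior
    equilibrium; otherwise the linear-programming formulation decides,
    and the verdict is reconciled with Kaplansky's certificate.
    Non-existence is reported in the result, not raised.
    """
    cert = is_completely_mixed(T)
    n = T.n
    _, s, Vh = np.linalg.svd(T.rates)
    smax = s[0] if s.size else 0.0
    null_dim = int(np.sum(s <= 1e-9 * max(smax, 1.0)))
    if null_dim == 1:
        v = Vh[-1]
        if np.all(v > 0) or np.all(v < 0):
            y = np.abs(v) / np.abs(v).sum()
            resid = float(np.abs(T.rates @ y).max())
            if cert.completely_mixed and resid <= max(tol, 1e-9):
                return NashResult(strategy=y, completely_mixed=True,
                                  certificate=cert, residual=resid,
                                  method="nullspace")
    # degenerate or boundary case: fall back to the LP
    x, _ = lp_equilibrium(T)
    resid = float(np.abs(np.minimum(T.rates @ x, 0.0)).max())
    interior = bool(np.all(x > tol)) and cert.completely_mixed
    return NashResult(strategy=x, completely_mixed=interior,
                      certificate=cert, residual=resid, method="lp")


def ne_closed_form_3(a: float, b: float, c: float) -> np.ndarray:
    """Interior equilibrium of the three-species cyclic tournament.

    For ``T = [[0, c, -b], [-c, 0, a], [b, -a, 0]]`` the game is
    completely mixed iff ``a, b, c`` are nonzero with a common sign, and
    the equilibrium is ``(a, b, c) / (a + b + c)``.
    """
    v = np.array([a, b, c], dtype=float)
    if np.any(v == 0) or not (np.all(v > 0) or np.all(v < 0)):
        raise ValueError("a, b, c must be nonzero and share a sign")
    return v / v.sum()


def _pfaffian_expressions_5(T: np.ndarray) -> np.ndarray:
    # the five 3-term alternating expressions in the entries of a 5x5
    # skew-symmetric matrix (sub-Pfaffians); the interior equilibrium,
    # when it exists, is proportional to them
    return np.array([
        T[1, 4] * T[2, 3] - T[2, 4] * T[1, 3] + T[3, 4] * T[1, 2],
        -T[0, 4] * T[2, 3] + T[2, 4] * T[0, 3] - T[3, 4] * T[0, 2],
        T[0, 4] * T[1, 3] - T[1, 4] * T[0, 3] + T[3, 4] * T[0, 1],
        -T[0, 4] * T[1, 2] + T[1, 4] * T[0, 2] - T[2, 4] * T[0, 1],
        T[0, 3] * T[1, 2] - T[1, 3] * T[0, 2] + T[2, 3] * T[0, 1],
    ])


def ne_closed_form_5(T: TournamentMatrix) -> NashResult:
    """Closed-form interior equilibrium of a five-species tournament.

    Evaluates the five sub-Pfaffian expressions; if they are nonzero and
    share a sign, the normalized vector is the completely mixed
    equilibrium.  Mixed signs mean no interior equilibrium exists, which
    is reported (not raised), consistently with Kaplansky's certificate.
    """
    if T.n != 5:
        raise ValueError(f"closed form requires n = 5, got n = {T.n}")
    e = _pfaffian_expressions_5(T.rates)
    cert = is_completely_mixed(T)
    if np.all(e > 0) or np.all(e < 0):
        y = e / e.sum()
        resid = float(np.abs(T.rates @ y).max())
        return NashResult(strategy=y, completely_mixed=True, certificate=cert,
                          residual=resid, method="closed_form_5")
    return NashResult(strategy=None, completely_mixed=False, certificate=cert,
                      method="closed_form_5")


def meanfield_lyapunov(x, y_star) -> float:
    """Relative entropy ``V(x) = -sum_i y*_i log(x_i / y*_i)``.

    Nonnegative on the open simplex by Gibbs' inequality, zero iff
    ``x == y_star``; a constant of motion of the replicator flow.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_star, dtype=float)
    if np.any(x <= 0):
        raise ValueError("V is defined on the open simplex: x must be strictly positive")
    if np.any(y <= 0):
        raise ValueError("reference point y_star must be strictly positive")
    return float(-np.sum(y * np.log(x / y)))


def simulate_meanfield(T: TournamentMatrix, x0, t_end: float,
                       n_samples: int = 1001, rtol: float = 1e-10,
                       atol: float = 1e-12, method: str = "DOP853",
                       y_star=None) -> MeanFieldTrajectory:
    """Integrate the single-patch replicator equation.

    Uses an adaptive high-order explicit scheme without any simplex
    re-projection, so conservation of the total and of ``V`` measures
    integrator quality rather than being enforced.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (T.n,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({T.n},)")
    if abs(x0.sum() - 1.0) > 1e-9 or np.any(x0 <= 0):
        raise ValueError("x0 must lie in the open unit simplex")

    def rhs(_t, x):
        return x * (T.rates @ x)

    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(rhs, (0.0, t_end), x0, method=method, rtol=rtol,
                    atol=atol, t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states = sol.y.T
    lyap = None
    if y_star is not None:
        lyap = np.array([meanfield_lyapunov(s, y_star) for s in states])
    return MeanFieldTrajectory(times=sol.t, states=states, lyapunov_values=lyap)
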