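"""Balanced metapopulation models: assembly, equilibrium, simulation, stability.

A *balanced metapopulation model* couples ``n`` species in tournament
competition (identical in every patch) with detailed-balanced migration
on a connected graph of ``m`` patches.  Writing ``x[i, j]`` for the
proportion of species ``i`` in patch ``j`` (the grand total over all
``n m`` entries is 1), the dynamics are

    dx[i,j]/dt = x[i,j] * (T Y* (p_j / y*))_i  -  (B K B.T (r_i / z*))_j

where ``p_j`` is patch ``j``'s species column, ``r_i`` species ``i``'s
patch row, ``y*`` the intra-patch coexistence equilibrium (``T y* = 0``),
``z*`` the thermodynamic equilibrium of the dispersal graph, and
``K = diag(kappa)`` the edge conductances.  The unique interior
equilibrium is the product ``x*[i, j] = y*_i z*_j``.  The relative
entropy ``V(x) = -sum x* log(x / x*)`` is non-increasing along
trajectories; LaSalle's principle then yields the stability dichotomy:
heterogeneous models (``z*`` non-uniform) converge to ``x*``, while
homogeneous models (``z*`` uniform) synchronize across patches and
settle on a neutral limit cycle of the single-patch replicator flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .dispersal import (
    BalanceCertificate,
    DispersalGraph,
    NotDetailedBalancedError,
    check_detailed_balance,
    classify_homogeneity,
)
from .tournaments import (
    KaplanskyCertificate,
    TournamentMatrix,
    nash_equilibrium,
)

__all__ = [
    "BalancedModel",
    "MetapopState",
    "Trajectory",
    "LongRunResult",
    "NotCompletelyMixedError",
    "assemble",
    "coexistence_equilibrium",
    "full_rhs",
    "general_rhs",
    "simulate",
    "lyapunov",
    "lyapunov_rate",
    "classify_longrun",
]


class NotCompletelyMixedError(ValueError):
    """Raised when the tournament admits no completely mixed equilibrium."""

    def __init__(self, message, certificate: KaplanskyCertificate | None = None):
        super().__init__(message)
        self.certificate = certificate


@dataclass(frozen=True)
class BalancedModel:
    """An assembled model with all equilibrium data precomputed."""

    tournament: TournamentMatrix
    graph: DispersalGraph
    y_star: np.ndarray
    z_star: np.ndarray
    kappas: np.ndarray
    balance: BalanceCertificate
    kaplansky: KaplanskyCertificate
    homogeneity: str

    @property
    def n(self) -> int:
        return self.tournament.n

    @property
    def m(self) -> int:
        return self.graph.m

    @property
    def x_star(self) -> np.ndarray:
        return np.outer(self.y_star, self.z_star)


@dataclass(frozen=True)
class MetapopState:
    """Proportions ``x[i, j]`` of species i in patch j at one time point."""

    proportions: np.ndarray  # (n, m)
    time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "proportions",
                           np.asarray(self.proportions, dtype=float))

    def patch(self, j: int) -> np.ndarray:
        """Species column ``p_j`` of patch ``j`` (0-based)."""
        return self.proportions[:, j]

    def species(self, i: int) -> np.ndarray:
        """Patch row ``r_i`` of species ``i`` (0-based)."""
        return self.proportions[i, :]

    def validate(self, tol: float = 1e-8) -> None:
        x = self.proportions
        if np.any(x < -tol) or np.any(x > 1 + tol):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(x.sum() - 1.0) > tol:
            raise ValueError(f"grand total is {x.sum()}, expected 1")


@dataclass
class Trajectory:
    """Sampled solution of the metapopulation ODE with diagnostics."""

    times: np.ndarray                 # (k,)
    states: np.ndarray                # (k, n, m)
    lyapunov_values: np.ndarray       # (k,)
    diagnostics: dict = field(default_factory=dict)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class LongRunResult:
    """Long-run classification of a trajectory.

    ``persistence_assumed`` flags that no species' persistence was
    verified: the classification reports local behavior under the
    standing assumption that interior trajectories stay interior.
    """

    label: str  # converged | limit_cycle_synchronized | undetermined
    distance_to_equilibrium: float
    cross_patch_spread: float
    lyapunov_final: float
    lyapunov_plateau_change: float
    persistence_assumed: bool = True


def assemble(T: TournamentMatrix, G: DispersalGraph,
             homogeneity_tol: float = 1e-9) -> BalancedModel:
    """Assemble a balanced model, rejecting anything outside the class.

    Raises
    ------
    NotCompletelyMixedError
        If the tournament has no completely mixed equilibrium (always
        the case for an even number of species); carries the
        rank/cofactor certificate.
    NotDetailedBalancedError
        If the dispersal graph is not detailed balanced; carries the
        balance certificate with its residuals.
    """
    nash = nash_equilibrium(T)
    if not nash.completely_mixed:
        raise NotCompletelyMixedError(
            f"tournament on {T.n} species admits no completely mixed equilibrium "
            f"(rank {nash.certificate.rank}, cofactor sign {nash.certificate.sign:+d})",
            certificate=nash.certificate,
        )
    balance = check_detailed_balance(G)
    if not balance.balanced:
        raise NotDetailedBalancedError(
            f"dispersal graph is not detailed balanced (residual {balance.residual:.3g})",
            certificate=balance,
        )
    return BalancedModel(
        tournament=T,
        graph=G,
        y_star=nash.strategy,
        z_star=balance.z_star,
        kappas=balance.kappas,
        balance=balance,
        kaplansky=nash.certificate,
        homogeneity=classify_homogeneity(balance, tol=homogeneity_tol),
    )


def coexistence_equilibrium(model: BalancedModel) -> np.ndarray:
    """The unique interior equilibrium ``x*[i, j] = y*_i z*_j`` (grand total 1)."""
    return model.x_star


def full_rhs(model: BalancedModel, x) -> np.ndarray:
    """Time derivative in the balanced (compact) formulation.

    Replication term ``x[i,j] (T Y* (p_j / y*))_i`` plus migration term
    ``-(B K B.T (r_i / z*))_j``.  The grand total of the derivatives is
    zero, so the flow is tangent to the unit simplex.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n, model.m):
        raise ValueError(f"state has shape {x.shape}, expected ({model.n}, {model.m})")
    T = model.tournament.rates
    y = model.y_star
    z = model.z_star
    B = model.graph.incidence
    # replication, all patches at once: columns are TY*(p_j / y*)
    growth = T @ (y[:, None] * (x / y[:, None]))
    phi = x * growth
    # migration, all species at once: rows are B K B.T (r_i / z*)
    flux = (B @ (model.kappas[:, None] * (B.T @ (x / z[None, :]).T))).T
    return phi - flux


def general_rhs(T: TournamentMatrix, G: DispersalGraph, x) -> np.ndarray:
    """Time derivative in the general (Laplacian) formulation.

    ``x[i,j] (T p_j)_i - (L r_i)_j``; valid for any dispersal graph and
    used as the independent cross-check of :func:`full_rhs` on balanced
    models.
    """
    x = np.asarray(x, dtype=float)
    phi = x * (T.rates @ x)
    psi = -(G.laplacian @ x.T).T
    return phi + psi


def simulate(model: BalancedModel, x0, t_end: float, n_samples: int = 2001,
             rtol: float = 1e-10, atol: float = 1e-12,
             method: str = "DOP853") -> Trajectory:
    """Integrate the model from an interior state on the unit simplex.

    Adaptive explicit integration without simplex re-projection;
    conservation of the grand total over the run is a diagnostic of
    integrator quality, recorded in ``diagnostics['grand_total_drift']``.
    The relative entropy ``V`` is evaluated at every stored sample.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.n, model.m):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({model.n}, {model.m})")
    if abs(x0.sum() - 1.0) > 1e-9:
        raise ValueError(f"x0 grand total is {x0.sum()}, expected 1")
    if np.any(x0 <= 0):
        raise ValueError("x0 must be strictly interior")
    n, m = model.n, model.m

    def rhs(_t, flat):
        return full_rhs(model, flat.reshape(n, m)).ravel()

    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(rhs, (0.0, t_end), x0.ravel(), method=method,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    states = sol.y.T.reshape(-1, n, m)
    V = np.array([lyapunov(model, s) for s in states])
    drift = float(np.abs(states.sum(axis=(1, 2)) - 1.0).max())
    return Trajectory(times=sol.t, states=states, lyapunov_values=V,
                      diagnostics={"grand_total_drift": drift,
                                   "rtol": rtol, "atol": atol,
                                   "method": method})


def lyapunov(model: BalancedModel, x) -> float:
    """Relative entropy ``V(x) = -sum_{i,j} x*[i,j] log(x[i,j] / x*[i,j])``.

    Defined on the open simplex only: states with a nonpositive entry
    raise rather than being clamped.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("V is defined on the open simplex: state must be strictly positive")
    xs = model.x_star
    return float(-np.sum(xs * np.log(x / xs)))


def lyapunov_rate(model: BalancedModel, x) -> float:
    """Time derivative of V along the flow (never positive).

    ``dV/dt = sum_i y*_i (z*/r_i).T B K B.T (r_i/z*)``, which is
    nonpositive and vanishes iff every species' patch profile is
    proportional to ``z*``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("rate is defined on the open simplex")
    B = model.graph.incidence
    z = model.z_star
    total = 0.0
    for i in range(model.n):
        u = x[i, :] / z
        total += model.y_star[i] * float((1.0 / u) @ (B @ (model.kappas * (B.T @ u))))
    return total


def classify_longrun(model: BalancedModel, trajectory: Trajectory,
                     tol: float = 1e-6, cycle_distance: float = 1e-2,
                     plateau_rtol: float = 1e-8, tail_fraction: float = 0.1
                     ) -> LongRunResult:
    """Classify the long-run behavior of a simulated trajectory.

    ``converged``
        The final state is within ``tol`` (max norm) of the coexistence
        equilibrium (heterogeneous models, or a start at the equilibrium).
    ``limit_cycle_synchronized``
        Cross-patch spread ``max_{i,j,k} |x[i,j] - x[i,k]|`` has fallen
        below ``tol`` while the distance to the equilibrium stays above
        ``cycle_distance`` over the trailing window and V has settled on
        a positive plateau (homogeneous models).
    ``undetermined``
        Anything else, typically a trajectory that is still in its
        transient.
    """
    xs = model.x_star
    tail = max(2, int(len(trajectory.times) * tail_fraction))
    states_tail = trajectory.states[-tail:]
    dist_end = float(np.abs(trajectory.final_state - xs).max())
    spread_end = float(
        (trajectory.final_state.max(axis=1) - trajectory.final_state.min(axis=1)).max()
    )
    V_tail = trajectory.lyapunov_values[-tail:]
    V_final = float(V_tail[-1])
    plateau_change = float(abs(V_tail.max() - V_tail.min()) / max(V_final, 1e-300))

    if dist_end < tol:
        label = "converged"
    else:
        dist_tail = np.abs(states_tail - xs).reshape(tail, -1).max(axis=1)
        synchronized = spread_end < tol
        away = bool(np.all(dist_tail > cycle_distance))
        plateau = plateau_change < plateau_rtol and V_final > 0
        label = "limit_cycle_synchronized" if (synchronized and away and plateau) \
            else "undetermined"
    return LongRunResult(
        label=label,
        distance_to_equilibrium=dist_end,
        cross_patch_spread=spread_end,
        lyapunov_final=V_final,
        lyapunov_plateau_change=plateau_change,
    )
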