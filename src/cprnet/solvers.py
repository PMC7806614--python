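"""Exact extraction states: Nash equilibria, Pareto efficient states, and
reallocation steady states.

All three states are characterized by complementarity (KKT) conditions of
concave quadratic programs:

* **Nash** — the game admits an exact potential

      P(q) = sum_s [alpha*p(s) - beta(s)*p(s)^2/2 - beta(s)/2 * sum_a q(a,s)^2]
             - gamma/2 * sum_a total(a)^2,

  whose gradient along each edge equals that agent's marginal payoff; its
  unique maximizer over q >= 0 is the Nash state.  The program is strictly
  concave, so it is solved *exactly* by Cholesky factorization plus
  nonnegative least squares.
* **Pareto** — maximize collective wealth ``F = sum_a f(a)``; at gamma=0 the
  split of a source's optimal pressure among its users is degenerate, and
  the minimum-Euclidean-norm maximizer is returned (tiny Tikhonov ridge).
* **Steady state** — maximize ``sum_s [alpha*p(s) - beta(s)*p(s)^2/2]``
  subject to each agent keeping its initial total effort.  The KKT
  conditions say exactly that no agent sees a quality gradient it can still
  exploit: every source an agent actively uses sits at that agent's maximal
  affiliated quality.  Solved by FISTA with per-agent simplex projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import nnls

from .game import ExtractionState, GameParams, quality, payoffs, resolve_beta
from .network import BipartiteNetwork

__all__ = [
    "SolverReport",
    "nash_equilibrium",
    "pareto_efficient",
    "steady_state_lcp",
    "best_response",
    "best_response_iteration",
]


@dataclass(frozen=True)
class SolverReport:
    """Outcome of a state computation."""

    state: ExtractionState
    objective: float
    kkt_residual: float
    iterations: int
    converged: bool


# ---------------------------------------------------------------------------
# quadratic forms on the edge space
# ---------------------------------------------------------------------------


def _edge_indicators(network: BipartiteNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Dense one-hot edge->agent and edge->source incidence matrices."""
    E = network.E
    A_ind = np.zeros((E, network.M))
    S_ind = np.zeros((E, network.N))
    A_ind[np.arange(E), network.agent_of_edge] = 1.0
    S_ind[np.arange(E), network.source_of_edge] = 1.0
    return A_ind, S_ind


def _nash_system(network: BipartiteNetwork, params: GameParams) -> tuple[np.ndarray, np.ndarray]:
    """Matrix/vector (A, c) with marginal payoff g(q) = c - A q per edge."""
    beta_s = resolve_beta(network, params)
    A_ind, S_ind = _edge_indicators(network)
    A = (S_ind * beta_s) @ S_ind.T
    A[np.diag_indices_from(A)] += beta_s[network.source_of_edge]
    if params.gamma > 0:
        A += params.gamma * (A_ind @ A_ind.T)
    c = np.full(network.E, params.alpha)
    return A, c


def _welfare_system(network: BipartiteNetwork, params: GameParams) -> tuple[np.ndarray, np.ndarray]:
    """(H, c) with collective wealth F(q) = c.q - q.H.q/2."""
    beta_s = resolve_beta(network, params)
    A_ind, S_ind = _edge_indicators(network)
    H = 2.0 * (S_ind * beta_s) @ S_ind.T
    if params.gamma > 0:
        H += params.gamma * (A_ind @ A_ind.T)
    c = np.full(network.E, params.alpha)
    return H, c


def _nnls_qp(A: np.ndarray, c: np.ndarray) -> np.ndarray:
    """argmax of c.q - q.A.q/2 over q >= 0 for SPD A, via Cholesky + NNLS."""
    L = np.linalg.cholesky(A)
    z = solve_triangular(L, c, lower=True)
    q, _ = nnls(L.T, z)
    return q


def _complementarity_residual(q: np.ndarray, g: np.ndarray, active_tol: float = 1e-11) -> float:
    """KKT residual: g <= 0 everywhere, g = 0 wherever q > 0."""
    res_free = np.abs(g[q > active_tol]).max(initial=0.0)
    res_bound = g[q <= active_tol].max(initial=0.0)
    return float(max(res_free, res_bound))


# ---------------------------------------------------------------------------
# Nash and Pareto
# ---------------------------------------------------------------------------


def nash_equilibrium(
    network: BipartiteNetwork, params: GameParams, tol: float = 1e-9
) -> SolverReport:
    """The game's unique Nash equilibrium.

    Every edge satisfies ``q >= 0``, marginal payoff
    ``alpha - beta(s)*(p(s) + q(a,s)) - gamma*total(a) <= 0``, and their
    product is zero.  Uniqueness follows from strict concavity of the exact
    potential.
    """
    A, c = _nash_system(network, params)
    q = _nnls_qp(A, c)
    g = c - A @ q
    res = _complementarity_residual(q, g)
    objective = float(c @ q - 0.5 * q @ A @ q)
    return SolverReport(
        state=ExtractionState(network, q),
        objective=objective,
        kkt_residual=res,
        iterations=1,
        converged=res <= tol,
    )


def pareto_efficient(
    network: BipartiteNetwork, params: GameParams, tol: float = 1e-8, ridge: float | None = None
) -> SolverReport:
    """Collective-wealth maximizer over the nonnegative orthant.

    At gamma=0 the maximizer is unique only in the source pressures; the
    minimum-norm allocation (equal split among a source's users) is selected
    by a vanishing Tikhonov ridge.  The KKT residual reported is for the
    *unridged* welfare program.
    """
    H, c = _welfare_system(network, params)
    if ridge is None:
        ridge = 1e-10 * float(resolve_beta(network, params).mean())
    A = H + ridge * np.eye(network.E)
    q = _nnls_qp(A, c)
    g = c - H @ q
    res = _complementarity_residual(q, g, active_tol=1e-9)
    objective = float(c @ q - 0.5 * q @ H @ q)
    return SolverReport(
        state=ExtractionState(network, q),
        objective=objective,
        kkt_residual=res,
        iterations=1,
        converged=res <= tol,
    )


# ---------------------------------------------------------------------------
# steady states under conserved per-agent totals
# ---------------------------------------------------------------------------


def _project_rows_to_simplexes(
    v: np.ndarray, offsets: np.ndarray, agent_of_edge: np.ndarray, totals: np.ndarray
) -> np.ndarray:
    """Euclidean projection of v onto {q >= 0, per-agent row sums = totals}.

    Vectorized simplex projection over the contiguous per-agent edge groups
    (edges are in canonical agent-major order).
    """
    E = v.size
    order = np.lexsort((-v, agent_of_edge))
    vs = v[order]
    cs = np.cumsum(vs)
    starts = offsets[:-1]
    sizes = np.diff(offsets)
    group_base = np.concatenate(([0.0], cs[starts[1:] - 1]))
    cs_group = cs - np.repeat(group_base, sizes)  # within-group cumsum
    pos = np.arange(E) - np.repeat(starts, sizes)
    t_edge = (cs_group - totals[agent_of_edge]) / (pos + 1.0)
    cond = vs - t_edge > 0
    idx = np.where(cond, np.arange(E), -1)
    rho = np.maximum.reduceat(idx, starts)
    # rho == -1 can only happen for totals <= 0; those rows project to zero
    theta = np.where(rho >= 0, t_edge[np.maximum(rho, 0)], 0.0)
    out_sorted = np.maximum(vs - theta[agent_of_edge], 0.0)
    zero_rows = totals <= 0
    if zero_rows.any():
        out_sorted[zero_rows[agent_of_edge]] = 0.0
    out = np.empty(E)
    out[order] = out_sorted
    return out


def steady_state_complementarity(
    state: ExtractionState, params: GameParams
) -> float:
    """Residual of the no-exploitable-gradient condition.

    For each agent, let mu(a) be the best quality among its sources; the
    steady-state contract requires q(a,s) = 0 on any source with
    b(s) < mu(a).  The residual is ``max_e min(q_e, mu(a)-b(s))``.
    """
    net = state.network
    b = quality(state, params)
    b_edge = b[net.source_of_edge]
    offsets = net.agent_edge_slices()
    mu = np.maximum.reduceat(b_edge, offsets[:-1])
    gap = mu[net.agent_of_edge] - b_edge
    return float(np.minimum(state.q, gap).max(initial=0.0))


def steady_state_lcp(
    network: BipartiteNetwork,
    params: GameParams,
    initial: ExtractionState,
    tol: float = 1e-11,
    max_iter: int = 200_000,
) -> SolverReport:
    """Reallocation steady state reached from ``initial``'s per-agent totals.

    Solves max_q sum_s [alpha*p(s) - beta(s)p(s)^2/2] subject to q >= 0 and
    each agent's total equal to its initial total, by FISTA with adaptive
    restart.  The maximizer's source pressures are unique; the complementarity
    contract (quality b(s) equal to the agent's top affiliated quality on
    every actively used edge) is verified and reported as the residual.
    """
    if initial.network is not network:
        if initial.network.edges() != network.edges():
            raise ValueError("initial state is defined on a different network")
    totals = initial.agent_totals
    if (totals < -1e-12).any():
        raise ValueError("per-agent totals must be nonnegative")
    beta_s = resolve_beta(network, params)
    s_idx = network.source_of_edge
    a_idx = network.agent_of_edge
    offsets = network.agent_edge_slices()
    lip = float((beta_s * network.source_degrees).max())

    def grad(qv: np.ndarray) -> np.ndarray:
        pressure = np.bincount(s_idx, weights=qv, minlength=network.N)
        return beta_s[s_idx] * pressure[s_idx] - params.alpha  # = -b per edge

    q = _project_rows_to_simplexes(initial.q.copy(), offsets, a_idx, totals)
    y = q.copy()
    t_mom = 1.0
    n_iter = 0
    res = np.inf
    check_every = 50
    for n_iter in range(1, max_iter + 1):
        q_new = _project_rows_to_simplexes(y - grad(y) / lip, offsets, a_idx, totals)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
        dq = q_new - q
        # adaptive restart on momentum overshoot
        if float((y - q_new) @ dq) > 0:
            y = q_new.copy()
            t_new = 1.0
        else:
            y = q_new + ((t_mom - 1.0) / t_new) * dq
        q, t_mom = q_new, t_new
        if n_iter % check_every == 0:
            res = steady_state_complementarity(ExtractionState(network, q), params)
            if res <= tol:
                break
    state = ExtractionState(network, q)
    res = steady_state_complementarity(state, params)
    pressure = state.source_pressures
    objective = float((params.alpha * pressure - 0.5 * beta_s * pressure**2).sum())
    return SolverReport(
        state=state,
        objective=objective,
        kkt_residual=res,
        iterations=n_iter,
        converged=res <= tol,
    )


# ---------------------------------------------------------------------------
# best responses (used as an independent oracle and for the not-Nash check)
# ---------------------------------------------------------------------------


def best_response(
    state: ExtractionState, params: GameParams, agent: int
) -> tuple[np.ndarray, float]:
    """Agent's payoff-maximizing efforts with all other agents frozen.

    Returns ``(q_agent, payoff)`` for the agent's edges (canonical order).
    The subproblem is a small strictly concave QP solved exactly by NNLS.
    """
    net = state.network
    beta_s = resolve_beta(net, params)
    offsets = net.agent_edge_slices()
    sl = slice(offsets[agent], offsets[agent + 1])
    own_sources = net.source_of_edge[sl]
    pressure = state.source_pressures
    others = pressure[own_sources] - state.q[sl]
    c = params.alpha - beta_s[own_sources] * others
    A = np.diag(2.0 * beta_s[own_sources]) + params.gamma
    q_a = _nnls_qp(A, c)
    payoff = float(c @ q_a - 0.5 * q_a @ A @ q_a)
    return q_a, payoff


def best_response_iteration(
    network: BipartiteNetwork,
    params: GameParams,
    tol: float = 1e-12,
    max_rounds: int = 10_000,
) -> ExtractionState:
    """Nash state by round-robin best-response iteration (independent oracle).

    Converges for this game because best-response updates monotonically
    increase the exact potential, which is bounded above.
    """
    state = ExtractionState.zeros(network)
    offsets = network.agent_edge_slices()
    q = state.q.copy()
    for _ in range(max_rounds):
        moved = 0.0
        for a in range(network.M):
            state = ExtractionState(network, q)
            q_a, _ = best_response(state, params, a)
            sl = slice(offsets[a], offsets[a + 1])
            moved = max(moved, float(np.abs(q_a - q[sl]).max(initial=0.0)))
            q[sl] = q_a
        if moved < tol:
            break
    return ExtractionState(network, q)
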