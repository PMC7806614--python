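"""Myopic reallocation dynamics.

Each agent continuously shifts effort from its lower-quality sources toward
its higher-quality ones at a rate proportional to the quality differences:

    dq(a,s)/dt = k * sum_{s' in S_a} [b(s) - b(s')]
               = k * (m(a)*b(s) - sum_{s' in S_a} b(s')).

The flow conserves every agent's total effort exactly (row sums of the
derivative vanish) and, in the interior, monotonically increases cost-free
collective wealth until all sources an agent uses share one quality value.

Nonnegativity is enforced by projected (Euler) steps: the raw step is taken
and the result is projected back onto each agent's scaled simplex
{q >= 0, sum = conserved total}.  In the interior this coincides with the
raw rule exactly; at the boundary its fixed points are precisely the
complementarity steady states (every actively used source sits at the
agent's top affiliated quality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game import ExtractionState, GameParams, resolve_beta
from .network import BipartiteNetwork
from .solvers import _project_rows_to_simplexes

__all__ = ["DynamicsConfig", "DynamicsTrace", "reallocation_rhs", "integrate"]


@dataclass(frozen=True)
class DynamicsConfig:
    """Integration settings.

    Parameters
    ----------
    k
        Reallocation rate constant; a pure time scale (fixed points are
        k-invariant).
    dt
        Euler step.  ``None`` selects a scheme-dependent default:
        ``0.01 / (k * max beta * max m)`` for ``explicit_euler``, or a step
        near the stability limit estimated from the linearized flow's
        spectral radius for ``adaptive``.
    t_max
        Integration horizon.
    tol
        Convergence threshold on the steady-state complementarity residual
        ``max_e min(q_e, mu(a) - b(s))`` (mu(a): the agent's best affiliated
        quality).  The raw within-agent quality gap is *not* a convergence
        measure: at a pinned steady state an agent that has fully abandoned
        a degraded source retains a permanent quality gap.
    scheme
        ``"explicit_euler"`` (fixed conservative step) or ``"adaptive"``
        (spectrally chosen step; typically 10-100x faster).
    record_every
        Trace sampling stride, in steps.
    """

    k: float = 1.0
    dt: float | None = None
    t_max: float = 1e4
    tol: float = 1e-8
    scheme: str = "explicit_euler"
    record_every: int = 50

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.scheme not in ("explicit_euler", "adaptive"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class DynamicsTrace:
    """Sampled trajectory diagnostics."""

    times: np.ndarray
    quality_spread: np.ndarray
    wealth: np.ndarray  # cost-free convention: sum_s pressure*quality
    wealth_total: np.ndarray  # including quadratic costs
    convergence_time: float | None
    converged: bool
    final_state: ExtractionState


def reallocation_rhs(
    state: ExtractionState, params: GameParams, k: float = 1.0
) -> np.ndarray:
    """Raw (unprojected) time derivative of every edge effort.

    Per-agent row sums are exactly zero; agents with a single source never
    move.
    """
    net = state.network
    beta_s = resolve_beta(net, params)
    b = params.alpha - beta_s * state.source_pressures
    b_edge = b[net.source_of_edge]
    sum_b_agent = np.bincount(net.agent_of_edge, weights=b_edge, minlength=net.M)
    m_edge = net.agent_degrees[net.agent_of_edge]
    return k * (m_edge * b_edge - sum_b_agent[net.agent_of_edge])


def _spectral_step(network: BipartiteNetwork, params: GameParams, k: float) -> float:
    """Step near the Euler stability limit of the linearized flow.

    The Jacobian is ``-k P H`` with P the per-agent graph-Laplacian-like
    block (eigenvalues in {0, m(a)}) and H the source coupling; its spectrum
    is real and nonpositive, so Euler is stable for dt < 2/rho.  The
    spectral radius is estimated by power iteration (deterministic start).
    """
    beta_s = resolve_beta(network, params)
    a_idx, s_idx = network.agent_of_edge, network.source_of_edge
    m_edge = network.agent_degrees[a_idx]
    rng = np.random.Generator(np.random.PCG64(0))
    v = rng.standard_normal(network.E)
    lam = 1.0
    for _ in range(60):
        pressure = np.bincount(s_idx, weights=v, minlength=network.N)
        db = -(beta_s * pressure)
        db_edge = db[s_idx]
        sum_db = np.bincount(a_idx, weights=db_edge, minlength=network.M)
        w = -(m_edge * db_edge - sum_db[a_idx])  # = +PHv
        lam = float(np.linalg.norm(w))
        if lam == 0:
            return 0.01 / k
        v = w / lam
    return 1.0 / (k * lam)


def integrate(
    initial: ExtractionState, params: GameParams, config: DynamicsConfig
) -> DynamicsTrace:
    """Integrate the projected reallocation flow until the quality spread
    falls below ``config.tol`` or ``t_max`` is reached.

    Per-agent totals are conserved along the whole trajectory (a
    multiplicative renormalization every 1000 steps removes accumulated
    floating-point drift).
    """
    net = initial.network
    beta_s = resolve_beta(net, params)
    a_idx, s_idx = net.agent_of_edge, net.source_of_edge
    offsets = net.agent_edge_slices()
    starts = offsets[:-1]
    m_edge = net.agent_degrees[a_idx]
    totals = initial.agent_totals
    safe_totals = np.where(totals > 0, totals, 1.0)
    k = config.k

    if config.dt is not None:
        dt = config.dt
    elif config.scheme == "adaptive":
        dt = _spectral_step(net, params, k)
    else:
        dt = 0.01 / (k * float(beta_s.max()) * float(net.agent_degrees.max()))

    q = initial.q.copy()
    t = 0.0
    times: list[float] = []
    spreads: list[float] = []
    wealth: list[float] = []
    wealth_tot: list[float] = []
    conv_time: float | None = None
    max_steps = int(np.ceil(config.t_max / dt))

    def diagnostics(q: np.ndarray, b_edge: np.ndarray, pressure: np.ndarray, b: np.ndarray):
        mu = np.maximum.reduceat(b_edge, starts)
        residual = float(np.minimum(q, mu[a_idx] - b_edge).max(initial=0.0))
        spread_a = mu - np.minimum.reduceat(b_edge, starts)
        spread = float(spread_a.max(initial=0.0))
        w0 = float((pressure * b).sum())
        cost = 0.5 * params.gamma * float((totals**2).sum())
        return residual, spread, w0, w0 - cost

    step = 0
    while True:
        pressure = np.bincount(s_idx, weights=q, minlength=net.N)
        b = params.alpha - beta_s * pressure
        b_edge = b[s_idx]
        residual, spread, w0, wt = diagnostics(q, b_edge, pressure, b)
        if step % config.record_every == 0 or residual < config.tol or step >= max_steps:
            times.append(t)
            spreads.append(spread)
            wealth.append(w0)
            wealth_tot.append(wt)
        if residual < config.tol:
            conv_time = t
            break
        if step >= max_steps:
            break

        sum_b = np.bincount(a_idx, weights=b_edge, minlength=net.M)
        d = k * (m_edge * b_edge - sum_b[a_idx])
        q = q + dt * d
        if q.min() < 0.0:
            # projected Euler: back onto each agent's conserved simplex
            q = _project_rows_to_simplexes(q, offsets, a_idx, totals)
        step += 1
        t = step * dt
        if step % 1000 == 0:
            row = np.bincount(a_idx, weights=q, minlength=net.M)
            q *= (totals / np.where(row > 0, row, 1.0))[a_idx]

    return DynamicsTrace(
        times=np.asarray(times),
        quality_spread=np.asarray(spreads),
        wealth=np.asarray(wealth),
        wealth_total=np.asarray(wealth_tot),
        convergence_time=conv_time,
        converged=conv_time is not None,
        final_state=ExtractionState(net, q),
    )
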