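"""Extraction states, payoffs, collective wealth, and inequality metrics.

The game: each agent ``a`` exerts a nonnegative extraction effort ``q(a,s)``
on every source ``s`` it is affiliated with.  A source's quality (benefit
per unit effort) degrades linearly with the total pressure on it,

    b(s) = alpha - beta(s) * pressure(s),

and an agent's payoff is its extracted benefit minus a quadratic cost
representing diminishing marginal utility,

    f(a) = sum_s q(a,s) * b(s) - (gamma/2) * total(a)**2.

Quality is deliberately *not* floored at zero: over-exploitation drives
``b(s)`` negative, and the equilibrium/steady-state solvers rely on the
unclipped linear form.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .network import BipartiteNetwork

__all__ = [
    "GameParams",
    "ExtractionState",
    "resolve_beta",
    "quality",
    "payoffs",
    "collective_wealth",
    "gini",
    "steady_state_quality",
    "steady_wealth",
    "write_state",
    "read_state",
]


@dataclass(frozen=True)
class GameParams:
    """Game parameters.

    Parameters
    ----------
    alpha
        Benefit per unit effort from a pristine source (> 0).
    gamma
        Coefficient of the quadratic extraction cost (>= 0); 0 means
        cost-free extraction.
    scenario
        ``"uniform"``: every source degrades with the same slope ``beta``.
        ``"degree_proportional"``: ``beta(s) = beta0 * <n> / n(s)``, so a
        source degrades in proportion to pressure *per user*.
    beta, beta0
        Slope constants for the two scenarios (> 0).
    """

    alpha: float = 1.0
    gamma: float = 0.0
    scenario: str = "uniform"
    beta: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.scenario not in ("uniform", "degree_proportional"):
            raise ValueError(f"unknown capacity scenario {self.scenario!r}")
        if self.scenario == "uniform" and self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.scenario == "degree_proportional" and self.beta0 <= 0:
            raise ValueError("beta0 must be > 0")

    def with_gamma(self, gamma: float) -> "GameParams":
        return replace(self, gamma=gamma)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "gamma": self.gamma,
            "scenario": self.scenario,
            "beta": self.beta,
            "beta0": self.beta0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GameParams":
        return cls(**d)


def resolve_beta(network: BipartiteNetwork, params: GameParams) -> np.ndarray:
    """Per-source degradation slope ``beta(s)`` under the chosen capacity scenario."""
    if params.scenario == "uniform":
        return np.full(network.N, params.beta)
    mean_n = network.mean_source_degree
    return params.beta0 * mean_n / network.source_degrees


@dataclass(frozen=True)
class ExtractionState:
    """Nonnegative extraction efforts, one per network edge (canonical edge order)."""

    network: BipartiteNetwork
    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (self.network.E,):
            raise ValueError(f"q must have one entry per edge ({self.network.E})")
        if q.min() < -1e-12:
            raise ValueError("extraction efforts must be nonnegative")
        object.__setattr__(self, "q", np.maximum(q, 0.0))

    @property
    def agent_totals(self) -> np.ndarray:
        """Row sums: each agent's total extraction effort."""
        return np.bincount(self.network.agent_of_edge, weights=self.q, minlength=self.network.M)

    @property
    def source_pressures(self) -> np.ndarray:
        """Column sums: total extraction pressure on each source."""
        return np.bincount(self.network.source_of_edge, weights=self.q, minlength=self.network.N)

    @property
    def total_extraction(self) -> float:
        """Q: population-wide total effort."""
        return float(self.q.sum())

    @classmethod
    def zeros(cls, network: BipartiteNetwork) -> "ExtractionState":
        return cls(network, np.zeros(network.E))


def quality(state: ExtractionState, params: GameParams) -> np.ndarray:
    """Source qualities ``b(s) = alpha - beta(s) * pressure(s)`` (may be negative)."""
    beta_s = resolve_beta(state.network, params)
    return params.alpha - beta_s * state.source_pressures


def payoffs(state: ExtractionState, params: GameParams) -> np.ndarray:
    """Per-agent payoffs ``f(a)``."""
    net = state.network
    b = quality(state, params)
    benefit = np.bincount(net.agent_of_edge, weights=state.q * b[net.source_of_edge], minlength=net.M)
    return benefit - 0.5 * params.gamma * state.agent_totals**2


def collective_wealth(
    state: ExtractionState, params: GameParams, include_costs: bool = True
) -> float:
    """Collective wealth.

    With ``include_costs`` (default) this is ``F = sum_a f(a)``.  Without,
    it is the cost-free benefit ``sum_s pressure(s) * b(s)`` — the quantity
    that reallocation alone can change, since each agent's total effort
    (hence its cost term) is conserved.
    """
    if include_costs:
        return float(payoffs(state, params).sum())
    b = quality(state, params)
    return float((state.source_pressures * b).sum())


def gini(values: np.ndarray) -> float:
    """Gini index ``G = sum_ij |v_i - v_j| / (2 n sum_i v_i)`` of a payoff vector.

    Raises
    ------
    ValueError
        If the values sum to <= 0 (the index is undefined there).
    Warns if any value is negative; the computation still proceeds.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("gini of an empty vector is undefined")
    total = v.sum()
    if total <= 0:
        raise ValueError("gini is undefined for values summing to <= 0")
    if (v < 0).any():
        warnings.warn("gini computed on negative values", stacklevel=2)
    vs = np.sort(v)
    n = v.size
    # O(n log n) identity for sum_ij |v_i - v_j|
    return float((2.0 * np.arange(1, n + 1) - n - 1.0) @ vs / (n * total))


def weighted_gini(values: np.ndarray, weights: np.ndarray) -> float:
    """Gini index of a discrete distribution (values with probability masses)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    mean = float(w @ v)
    if mean <= 0:
        raise ValueError("gini is undefined for a nonpositive mean")
    diff = np.abs(v[:, None] - v[None, :])
    return float(w @ diff @ w / (2.0 * mean))


def steady_state_quality(
    network: BipartiteNetwork, params: GameParams, source_pressures: np.ndarray
) -> np.ndarray:
    """Common quality each component relaxes to when reallocation equalizes it.

    For a connected component with sources ``S_c``,

        b_f = alpha - sum_{s in S_c} pressure(s) / sum_{s in S_c} 1/beta(s),

    i.e. the quality at which the component's conserved total pressure is
    redistributed so all its sources match.  Returns an array over sources
    holding each source's component value.
    """
    pressures = np.asarray(source_pressures, dtype=float)
    if (pressures < -1e-12).any():
        raise ValueError("pressures must be nonnegative")
    beta_s = resolve_beta(network, params)
    _, _, src_labels = network.components()
    b_f = np.empty(network.N)
    for c in np.unique(src_labels):
        mask = src_labels == c
        b_f[mask] = params.alpha - pressures[mask].sum() / (1.0 / beta_s[mask]).sum()
    return b_f


def steady_wealth(state: ExtractionState, params: GameParams) -> float:
    """Cost-free collective wealth after quality equalization, ``sum_c Q_c * b_f(c)``."""
    b_f = steady_state_quality(state.network, params, state.source_pressures)
    return float((state.source_pressures * b_f).sum())


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_state(state: ExtractionState, path: str | Path, params: GameParams | None = None) -> None:
    """Write a state as TSV ``agent_id<TAB>source_id<TAB>q`` (17 sig. digits).

    If ``params`` is given, a JSON sidecar ``<path>.json`` records them.
    """
    path = Path(path)
    net = state.network
    with path.open("w") as fh:
        fh.write("agent_id\tsource_id\tq\n")
        for a, s, q in zip(net.agent_of_edge, net.source_of_edge, state.q):
            fh.write(f"{a}\t{s}\t{q:.17g}\n")
    if params is not None:
        Path(str(path) + ".json").write_text(json.dumps(params.to_dict(), indent=2))


def read_state(path: str | Path, network: BipartiteNetwork) -> ExtractionState:
    """Read a state TSV back onto a known network (edges must match exactly)."""
    path = Path(path)
    q = np.zeros(network.E)
    key_to_idx = {
        (int(a), int(s)): i
        for i, (a, s) in enumerate(zip(network.agent_of_edge, network.source_of_edge))
    }
    seen = 0
    with path.open() as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["agent_id", "source_id", "q"]:
            raise ValueError(f"unexpected state header {header!r} in {path}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a_str, s_str, q_str = line.split("\t")[:3]
            key = (int(a_str), int(s_str))
            if key not in key_to_idx:
                raise ValueError(f"edge {key} in state file is not in the network")
            q[key_to_idx[key]] = float(q_str)
            seen += 1
    if seen != network.E:
        raise ValueError(f"state file has {seen} edges, network has {network.E}")
    return ExtractionState(network, q)
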