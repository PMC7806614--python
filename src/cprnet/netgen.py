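"""Generation of bipartite agent-source network ensembles.

Networks are drawn in two stages: first a degree sequence for each side from
one of the named degree-heterogeneity families, then a uniform-ish simple
bipartite graph realizing those sequences via configuration-model stub
pairing with double-edge-swap repair.

Degree families
---------------
Source side: ``D`` (delta function, all sources share one degree), ``N``
(integer-rounded normal, truncated at 1), ``PL`` (discrete power law with
exponent solved so the truncated mean hits the target).  Agent side: ``U``
(uniform, i.e. constant), ``R`` (random occupancy with binomial-like
margins), ``SF`` (scale-free-type, same discrete power-law family as
``PL``).  The canonical study ensembles combine one source family with one
agent family, e.g. ``"PL-SF"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .network import BipartiteNetwork, write_edge_list

__all__ = [
    "EnsembleSpec",
    "DegreeDistributions",
    "sample_degree_sequence",
    "build_bipartite",
    "generate_network",
    "generate_ensemble",
    "empirical_distributions",
    "SOURCE_KINDS",
    "AGENT_KINDS",
    "ENSEMBLE_LABELS",
]

SOURCE_KINDS = ("D", "N", "PL")
AGENT_KINDS = ("U", "R", "SF")
#: The nine canonical ensembles, labelled source-family "-" agent-family.
ENSEMBLE_LABELS = tuple(f"{s}-{a}" for s in SOURCE_KINDS for a in AGENT_KINDS)

_ALL_KINDS = set(SOURCE_KINDS) | set(AGENT_KINDS)


@dataclass(frozen=True)
class EnsembleSpec:
    """Specification of one network ensemble.

    ``M·mean_m`` must equal ``N·mean_n`` (both count the same edges).
    """

    source_dist: str
    agent_dist: str
    M: int = 50
    N: int = 50
    mean_m: float = 5.0
    mean_n: float = 5.0
    n_realizations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source_dist not in SOURCE_KINDS:
            raise ValueError(f"unknown source degree family {self.source_dist!r}")
        if self.agent_dist not in AGENT_KINDS:
            raise ValueError(f"unknown agent degree family {self.agent_dist!r}")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if abs(self.M * self.mean_m - self.N * self.mean_n) > 1e-9:
            raise ValueError(
                "edge-count mismatch: M*mean_m must equal N*mean_n "
                f"({self.M}*{self.mean_m} != {self.N}*{self.mean_n})"
            )

    @property
    def label(self) -> str:
        return f"{self.source_dist}-{self.agent_dist}"

    def to_dict(self) -> dict:
        return {
            "source_dist": self.source_dist,
            "agent_dist": self.agent_dist,
            "M": self.M,
            "N": self.N,
            "mean_m": self.mean_m,
            "mean_n": self.mean_n,
            "n_realizations": self.n_realizations,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleSpec":
        return cls(**d)


@dataclass(frozen=True)
class DegreeDistributions:
    """Degree probability mass functions ``P_A(m)``, ``P_S(n)`` for one ensemble."""

    P_A: dict[int, float]
    P_S: dict[int, float]

    def __post_init__(self) -> None:
        for name, pmf in (("P_A", self.P_A), ("P_S", self.P_S)):
            total = sum(pmf.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in pmf.values()):
                raise ValueError(f"{name} has negative mass")
            if any(d < 1 for d in pmf):
                raise ValueError(f"{name} has mass on degree < 1")

    @property
    def mean_m(self) -> float:
        return sum(m * p for m, p in self.P_A.items())

    @property
    def mean_n(self) -> float:
        return sum(n * p for n, p in self.P_S.items())

    @property
    def m_max(self) -> int:
        return max(self.P_A)

    @property
    def n_max(self) -> int:
        return max(self.P_S)

    def to_dict(self) -> dict:
        return {
            "P_A": {str(k): v for k, v in sorted(self.P_A.items())},
            "P_S": {str(k): v for k, v in sorted(self.P_S.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DegreeDistributions":
        return cls(
            P_A={int(k): float(v) for k, v in d["P_A"].items()},
            P_S={int(k): float(v) for k, v in d["P_S"].items()},
        )


# ---------------------------------------------------------------------------
# degree sequences
# ---------------------------------------------------------------------------


def _powerlaw_pmf(mean: float, d_max: int, tau_bounds=(-20.0, 60.0)) -> np.ndarray:
    """Discrete power law p(d) ∝ d^(−τ) on 1..d_max with given truncated mean."""
    d = np.arange(1, d_max + 1, dtype=float)

    def mean_of(tau: float) -> float:
        w = d ** (-tau)
        return float((d * w).sum() / w.sum())

    lo, hi = tau_bounds
    if not (mean_of(hi) <= mean <= mean_of(lo)):
        raise ValueError(f"target mean {mean} unreachable on support 1..{d_max}")
    tau = brentq(lambda t: mean_of(t) - mean, lo, hi, xtol=1e-12)
    w = d ** (-tau)
    return w / w.sum()


def sample_degree_sequence(
    kind: str,
    size: int,
    mean: float,
    rng: np.random.Generator,
    sigma: float = 1.5,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Draw a degree sequence of the given family.

    All degrees are >= 1 and the sample mean is within 5% of ``mean``
    (exact for the homogeneous families ``D``/``U`` and for ``R``, whose
    construction fixes the edge total).  For the stochastic families the
    5% contract is enforced by bounded resampling; this conditions the
    ensemble on its nominal mean degree, which is a stated property of the
    ensembles being emulated.

    Parameters
    ----------
    kind
        ``D``/``N``/``PL`` (source side) or ``U``/``R``/``SF`` (agent side).
    size
        Number of nodes on this side.
    mean
        Target mean degree (>= 1).
    sigma
        Standard deviation of the ``N`` family before rounding.
    """
    if kind not in _ALL_KINDS:
        raise ValueError(f"unknown degree family {kind!r}; expected one of {sorted(_ALL_KINDS)}")
    if size < 1:
        raise ValueError("size must be >= 1")
    if mean < 1:
        raise ValueError("mean degree must be >= 1")

    if kind in ("D", "U"):
        return np.full(size, int(round(mean)), dtype=np.int64)

    if kind == "R":
        total = int(round(size * mean))
        counts = rng.multinomial(total, np.full(size, 1.0 / size))
        # repair zero-degree nodes by moving stubs from degree>=2 nodes
        while (counts == 0).any():
            zero = np.flatnonzero(counts == 0)
            donors = np.flatnonzero(counts >= 2)
            take = rng.choice(donors, size=zero.size, replace=donors.size < zero.size)
            for z, t in zip(zero, take):
                if counts[t] >= 2:
                    counts[t] -= 1
                    counts[z] += 1
        return counts.astype(np.int64)

    d_max = max(size - 1, int(round(mean)) + 1)
    if kind == "N":
        def draw() -> np.ndarray:
            raw = np.rint(rng.normal(mean, sigma, size=size)).astype(np.int64)
            return np.clip(raw, 1, d_max)
    else:  # PL / SF
        pmf = _powerlaw_pmf(mean, d_max)
        support = np.arange(1, d_max + 1)

        def draw() -> np.ndarray:
            return rng.choice(support, size=size, p=pmf).astype(np.int64)

    for _ in range(max_attempts):
        seq = draw()
        if abs(seq.mean() - mean) <= 0.05 * mean:
            return seq
    raise RuntimeError(f"could not draw a {kind} sequence with mean within 5% of {mean}")


# ---------------------------------------------------------------------------
# graph realization
# ---------------------------------------------------------------------------


def _gale_ryser_feasible(agent_deg: np.ndarray, source_deg: np.ndarray) -> bool:
    """Gale-Ryser condition for a simple bipartite graph with these margins."""
    a = np.sort(agent_deg)[::-1]
    s = np.asarray(source_deg)
    if a.sum() != s.sum():
        return False
    for k in range(1, a.size + 1):
        if a[:k].sum() > np.minimum(s, k).sum():
            return False
    return True


def _reconcile_totals(
    agent_deg: np.ndarray,
    source_deg: np.ndarray,
    rng: np.random.Generator,
    max_steps: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Nudge degrees by ±1 at uniformly random nodes until totals match.

    Moves respect ``1 <= degree <= opposite-side size``.  Adjustments are
    applied on the agent side whenever possible so that the realized source
    degree distribution stays within its sampled family (ensembles sharing a
    source family must share P_S); the source side is only touched when the
    agent side is saturated.
    """
    a = agent_deg.copy()
    s = source_deg.copy()
    N, M = s.size, a.size
    for _ in range(max_steps):
        diff = int(a.sum() - s.sum())
        if diff == 0:
            return a, s
        if diff < 0:  # agents short of stubs: grow an agent, else shrink a source
            moves = [(a, np.flatnonzero(a < N), +1), (s, np.flatnonzero(s > 1), -1)]
        else:
            moves = [(a, np.flatnonzero(a > 1), -1), (s, np.flatnonzero(s < M), +1)]
        for arr, idx, delta in moves:
            if idx.size:
                arr[rng.choice(idx)] += delta
                break
        else:
            raise ValueError("degree sequences cannot be reconciled to a common edge total")
    raise ValueError("degree sequences cannot be reconciled to a common edge total")


def build_bipartite(
    agent_degrees: Sequence[int],
    source_degrees: Sequence[int],
    rng: np.random.Generator,
    max_swaps: int = 10_000,
    max_restarts: int = 3,
) -> BipartiteNetwork:
    """Realize a simple bipartite graph from two degree sequences.

    Unequal stub totals are first reconciled by random unit adjustments.
    The graph is then built by configuration-model stub pairing; duplicate
    edges are removed by random degree-preserving double-edge swaps, with a
    full re-pairing if a realization cannot be made simple within
    ``max_swaps`` swaps.

    Raises
    ------
    ValueError
        If no simple bipartite graph exists for the (reconciled) sequences.
    """
    a_deg = np.asarray(agent_degrees, dtype=np.int64)
    s_deg = np.asarray(source_degrees, dtype=np.int64)
    if a_deg.min() < 1 or s_deg.min() < 1:
        raise ValueError("all degrees must be >= 1")
    M, N = a_deg.size, s_deg.size
    if a_deg.max() > N or s_deg.max() > M:
        raise ValueError("degree exceeds the opposite side's size; no simple graph exists")
    if a_deg.sum() != s_deg.sum():
        a_deg, s_deg = _reconcile_totals(a_deg, s_deg, rng)
    if not _gale_ryser_feasible(a_deg, s_deg):
        raise ValueError("degree sequences are not bigraphical (Gale-Ryser violated)")

    agent_stubs = np.repeat(np.arange(M), a_deg)
    source_stubs = np.repeat(np.arange(N), s_deg)
    E = agent_stubs.size

    for _ in range(max_restarts):
        a_e = agent_stubs.copy()
        s_e = source_stubs[rng.permutation(E)]
        if _make_simple(a_e, s_e, N, rng, max_swaps):
            return BipartiteNetwork(M=M, N=N, agent_of_edge=a_e, source_of_edge=s_e)
    # Heavy-tailed sequences can defeat random repair; fall back to a greedy
    # (Havel-Hakimi-style) construction, which succeeds whenever Gale-Ryser
    # holds, then mix with degree-preserving double-edge swaps.
    a_e, s_e = _greedy_bipartite(a_deg, s_deg)
    _mix_edges(a_e, s_e, N, rng, n_attempts=10 * E)
    return BipartiteNetwork(M=M, N=N, agent_of_edge=a_e, source_of_edge=s_e)


def _make_simple(
    a_e: np.ndarray, s_e: np.ndarray, N: int, rng: np.random.Generator, max_swaps: int
) -> bool:
    """Remove duplicate edges in place via random double-edge swaps."""
    E = a_e.size
    counts: dict[tuple[int, int], int] = {}
    for a, s in zip(a_e.tolist(), s_e.tolist()):
        counts[(a, s)] = counts.get((a, s), 0) + 1
    dups = [e for e, c in counts.items() if c > 1]
    if not dups:
        return True
    for _ in range(max_swaps):
        pair = dups[rng.integers(len(dups))]
        # locate one occurrence of the duplicated pair
        occ = np.flatnonzero((a_e == pair[0]) & (s_e == pair[1]))
        i = int(occ[rng.integers(occ.size)])
        j = int(rng.integers(E))
        if i == j or a_e[i] == a_e[j] or s_e[i] == s_e[j]:
            continue
        new1 = (int(a_e[i]), int(s_e[j]))
        new2 = (int(a_e[j]), int(s_e[i]))
        if counts.get(new1, 0) or counts.get(new2, 0):
            continue
        old1 = (int(a_e[i]), int(s_e[i]))
        old2 = (int(a_e[j]), int(s_e[j]))
        for old in (old1, old2):
            counts[old] -= 1
        counts[new1] = counts.get(new1, 0) + 1
        counts[new2] = counts.get(new2, 0) + 1
        s_e[i], s_e[j] = s_e[j], s_e[i]
        dups = [e for e, c in counts.items() if c > 1]
        if not dups:
            return True
    return False


def _greedy_bipartite(a_deg: np.ndarray, s_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Connect agents in decreasing degree order to the highest-capacity sources."""
    order = np.argsort(-a_deg, kind="stable")
    remaining = s_deg.astype(np.int64).copy()
    edges_a, edges_s = [], []
    for a in order:
        d = int(a_deg[a])
        targets = np.argsort(-remaining, kind="stable")[:d]
        if remaining[targets[-1]] <= 0:
            raise ValueError("degree sequences are not bigraphical")
        for s in targets:
            edges_a.append(int(a))
            edges_s.append(int(s))
        remaining[targets] -= 1
    return np.asarray(edges_a, dtype=np.int64), np.asarray(edges_s, dtype=np.int64)


def _mix_edges(
    a_e: np.ndarray, s_e: np.ndarray, N: int, rng: np.random.Generator, n_attempts: int
) -> None:
    """Randomize a simple bipartite graph in place by double-edge swaps."""
    E = a_e.size
    edge_set = set(zip(a_e.tolist(), s_e.tolist()))
    for _ in range(n_attempts):
        i, j = rng.integers(E, size=2)
        if i == j or a_e[i] == a_e[j] or s_e[i] == s_e[j]:
            continue
        new1 = (int(a_e[i]), int(s_e[j]))
        new2 = (int(a_e[j]), int(s_e[i]))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((int(a_e[i]), int(s_e[i])))
        edge_set.discard((int(a_e[j]), int(s_e[j])))
        edge_set.add(new1)
        edge_set.add(new2)
        s_e[i], s_e[j] = s_e[j], s_e[i]


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


def generate_network(
    spec: EnsembleSpec, rng: np.random.Generator, max_attempts: int = 100
) -> BipartiteNetwork:
    """Draw one network realization from an ensemble specification.

    Degree-sequence pairs that admit no simple bipartite graph (possible for
    extreme heavy-tailed draws) are rejected; only the *agent* sequence is
    redrawn, so the realized source marginals stay unconditioned on
    feasibility (ensembles sharing a source family must share P_S).
    """
    s_deg = sample_degree_sequence(spec.source_dist, spec.N, spec.mean_n, rng)
    for attempt in range(max_attempts):
        a_deg = sample_degree_sequence(spec.agent_dist, spec.M, spec.mean_m, rng)
        try:
            return build_bipartite(a_deg, s_deg, rng)
        except ValueError:
            # last-resort escape hatch for a pathological source draw
            if attempt % 25 == 24:
                s_deg = sample_degree_sequence(spec.source_dist, spec.N, spec.mean_n, rng)
            continue
    raise RuntimeError(f"could not realize a network for {spec.label} after {max_attempts} draws")


def ensemble_rng(spec: EnsembleSpec, realization: int) -> np.random.Generator:
    """Deterministic per-realization generator: child ``realization`` of the spec seed."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(spec.seed, spawn_key=(realization,)))
    )


def generate_ensemble(spec: EnsembleSpec) -> list[BipartiteNetwork]:
    """Generate all realizations of an ensemble, reproducibly from its seed."""
    return [generate_network(spec, ensemble_rng(spec, r)) for r in range(spec.n_realizations)]


def empirical_distributions(networks: Sequence[BipartiteNetwork]) -> DegreeDistributions:
    """Pool degree histograms over networks into probability mass functions."""
    if not networks:
        raise ValueError("need at least one network")
    m_counts: dict[int, int] = {}
    n_counts: dict[int, int] = {}
    for net in networks:
        for d in net.agent_degrees:
            m_counts[int(d)] = m_counts.get(int(d), 0) + 1
        for d in net.source_degrees:
            n_counts[int(d)] = n_counts.get(int(d), 0) + 1
    m_tot = sum(m_counts.values())
    n_tot = sum(n_counts.values())
    return DegreeDistributions(
        P_A={k: v / m_tot for k, v in sorted(m_counts.items())},
        P_S={k: v / n_tot for k, v in sorted(n_counts.items())},
    )


def write_ensemble(spec: EnsembleSpec, out_dir: str | Path) -> list[Path]:
    """Generate an ensemble to disk: one TSV edge list per realization plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in range(spec.n_realizations):
        net = generate_network(spec, ensemble_rng(spec, r))
        p = out_dir / f"{spec.label}_{r:04d}.tsv"
        write_edge_list(net, p)
        paths.append(p)
    manifest = spec.to_dict() | {"files": [p.name for p in paths]}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return paths
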