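"""Bipartite agent-resource affiliation networks.

Agents (the extracting parties) and sources (the common-pool resources they
draw from) form the two sides of a simple bipartite graph.  The network is
static: it encodes who has access to what, and all game quantities are
indexed either by node or by edge.

Edges are stored in lexicographic ``(agent, source)`` order, which gives
every state vector a canonical layout and makes all downstream linear
algebra deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["BipartiteNetwork", "read_edge_list", "write_edge_list"]


@dataclass(frozen=True)
class BipartiteNetwork:
    """A simple bipartite graph of ``M`` agents and ``N`` sources.

    Parameters
    ----------
    M, N
        Number of agents and sources.  Agent ids run ``0..M-1`` and source
        ids ``0..N-1``.
    agent_of_edge, source_of_edge
        Parallel integer arrays of length ``E`` giving the endpoints of each
        edge, sorted lexicographically by ``(agent, source)``.

    Notes
    -----
    The constructor enforces the structural invariants of the model: edges
    are unique, every node has degree at least one (an agent with no source
    cannot play, a source with no user is outside the game), and the two
    degree sequences share the same total (each edge contributes one stub on
    either side).
    """

    M: int
    N: int
    agent_of_edge: np.ndarray
    source_of_edge: np.ndarray
    _agent_degrees: np.ndarray = field(init=False, repr=False, compare=False)
    _source_degrees: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.agent_of_edge, dtype=np.int64)
        s = np.asarray(self.source_of_edge, dtype=np.int64)
        if a.shape != s.shape or a.ndim != 1:
            raise ValueError("edge endpoint arrays must be 1-D and parallel")
        if a.size == 0:
            raise ValueError("network must contain at least one edge")
        if a.min() < 0 or a.max() >= self.M:
            raise ValueError("agent ids out of range")
        if s.min() < 0 or s.max() >= self.N:
            raise ValueError("source ids out of range")
        order = np.lexsort((s, a))
        a, s = a[order], s[order]
        key = a * self.N + s
        if np.any(np.diff(key) == 0):
            raise ValueError("duplicate edges are not allowed")
        m = np.bincount(a, minlength=self.M)
        n = np.bincount(s, minlength=self.N)
        if m.min() == 0:
            raise ValueError("isolated agents are not allowed")
        if n.min() == 0:
            raise ValueError("isolated sources are not allowed")
        object.__setattr__(self, "agent_of_edge", a)
        object.__setattr__(self, "source_of_edge", s)
        object.__setattr__(self, "_agent_degrees", m)
        object.__setattr__(self, "_source_degrees", n)

    # -- basic accessors ---------------------------------------------------

    @property
    def E(self) -> int:
        """Number of edges."""
        return int(self.agent_of_edge.size)

    @property
    def agent_degrees(self) -> np.ndarray:
        """m(a): number of sources affiliated with each agent."""
        return self._agent_degrees

    @property
    def source_degrees(self) -> np.ndarray:
        """n(s): number of agents affiliated with each source."""
        return self._source_degrees

    @property
    def mean_agent_degree(self) -> float:
        return self.E / self.M

    @property
    def mean_source_degree(self) -> float:
        return self.E / self.N

    def edges(self) -> list[tuple[int, int]]:
        return list(zip(self.agent_of_edge.tolist(), self.source_of_edge.tolist()))

    @classmethod
    def from_edges(cls, M: int, N: int, edges: Iterable[tuple[int, int]]) -> "BipartiteNetwork":
        pairs = np.asarray(list(edges), dtype=np.int64)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("edges must be (agent, source) pairs")
        return cls(M=M, N=N, agent_of_edge=pairs[:, 0], source_of_edge=pairs[:, 1])

    # -- structure ---------------------------------------------------------

    def agent_edge_slices(self) -> np.ndarray:
        """Offsets into the edge arrays delimiting each agent's edges.

        Because edges are sorted by agent, agent ``a`` owns the contiguous
        slice ``offsets[a]:offsets[a+1]``.
        """
        return np.concatenate(([0], np.cumsum(self._agent_degrees)))

    def components(self) -> tuple[int, np.ndarray, np.ndarray]:
        """Connected components of the bipartite graph.

        Returns ``(n_components, agent_labels, source_labels)``.
        """
        biadj = coo_matrix(
            (np.ones(self.E), (self.agent_of_edge, self.source_of_edge)),
            shape=(self.M, self.N),
        )
        from scipy.sparse import bmat

        adj = bmat([[None, biadj], [biadj.T, None]], format="csr")
        n_comp, labels = connected_components(adj, directed=False)
        return n_comp, labels[: self.M], labels[self.M :]


def write_edge_list(network: BipartiteNetwork, path: str | Path) -> None:
    """Write a network as a TSV edge list with an ``agent_id\tsource_id`` header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("agent_id\tsource_id\n")
        for a, s in zip(network.agent_of_edge, network.source_of_edge):
            fh.write(f"{a}\t{s}\n")


def read_edge_list(
    path: str | Path, M: int | None = None, N: int | None = None
) -> BipartiteNetwork:
    """Read a TSV edge list (``agent_id<TAB>source_id``, 0-based ids).

    ``M``/``N`` may be given explicitly; otherwise they are inferred as
    ``max id + 1`` on each side.  Bipartiteness and the structural
    invariants are validated by the :class:`BipartiteNetwork` constructor.
    """
    path = Path(path)
    rows: list[tuple[int, int]] = []
    with path.open() as fh:
        header = fh.readline().strip().split("\t")
        if header[:2] != ["agent_id", "source_id"]:
            raise ValueError(f"unexpected edge-list header {header!r} in {path}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            a_str, s_str = line.split("\t")[:2]
            rows.append((int(a_str), int(s_str)))
    if not rows:
        raise ValueError(f"empty edge list in {path}")
    arr = np.asarray(rows, dtype=np.int64)
    M = int(arr[:, 0].max()) + 1 if M is None else M
    N = int(arr[:, 1].max()) + 1 if N is None else N
    return BipartiteNetwork(M=M, N=N, agent_of_edge=arr[:, 0], source_of_edge=arr[:, 1])
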