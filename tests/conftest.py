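"""Shared fixtures: small random instances and the canonical ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from cprnet.game import ExtractionState, GameParams
from cprnet.netgen import (
    ENSEMBLE_LABELS,
    EnsembleSpec,
    build_bipartite,
    empirical_distributions,
    ensemble_rng,
    generate_network,
    sample_degree_sequence,
)
from cprnet.network import BipartiteNetwork

CANONICAL_SEED = 42
CANONICAL_REALIZATIONS = 100


def random_network(
    rng: np.random.Generator, M: int | None = None, N: int | None = None, mean: float = 3.0
) -> BipartiteNetwork:
    """A small random bipartite network (binomial-like margins on both sides)."""
    for _ in range(50):
        M_ = int(rng.integers(3, 12)) if M is None else M
        N_ = int(rng.integers(3, 12)) if N is None else N
        a_deg = sample_degree_sequence("R", M_, max(1.0, min(mean, N_)), rng)
        s_deg = sample_degree_sequence("R", N_, max(1.0, min(mean * M_ / N_, M_)), rng)
        try:
            return build_bipartite(a_deg, s_deg, rng)
        except ValueError:
            continue
    raise RuntimeError("could not draw a feasible random network")


def random_state(rng: np.random.Generator, network: BipartiteNetwork, scale: float = 1.0):
    return ExtractionState(network, rng.uniform(0, scale, size=network.E))


@pytest.fixture(scope="session")
def canonical_ensembles() -> dict[str, list[BipartiteNetwork]]:
    """All 9 study ensembles: M = N = 50, mean degrees 5, 100 realizations."""
    out = {}
    for label in ENSEMBLE_LABELS:
        src, ag = label.split("-")
        spec = EnsembleSpec(
            source_dist=src,
            agent_dist=ag,
            n_realizations=CANONICAL_REALIZATIONS,
            seed=CANONICAL_SEED,
        )
        out[label] = [
            generate_network(spec, ensemble_rng(spec, r))
            for r in range(CANONICAL_REALIZATIONS)
        ]
    return out


@pytest.fixture(scope="session")
def canonical_dists(canonical_ensembles):
    """Pooled degree distributions of the 9 ensembles."""
    return {
        label: empirical_distributions(nets)
        for label, nets in canonical_ensembles.items()
    }


@pytest.fixture()
def params0() -> GameParams:
    return GameParams(alpha=1.0, beta=1.0, gamma=0.0)
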