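# cprnet

Common-pool resource (CPR) extraction games on bipartite agent–resource
networks: exact equilibria, myopic reallocation dynamics, and heterogeneous
mean-field predictions.

## The problem

A common-pool resource — a fishery, pasture, aquifer, congested network
service — returns less benefit per unit effort as total usage rises. When a
population of agents extracts from *several* such resources through a
bipartite affiliation network, each agent faces an allocation problem on
top of the usual effort problem: how to split its effort among the
resources it can access. `cprnet` simulates and solves this game for
researchers studying how network structure shapes over-exploitation
("tragedy of the commons"), collective wealth, and inequality.

## The model

`M` agents and `N` sources form a static bipartite network; agent `a` of
degree `m(a)` exerts effort `q(a,s) ≥ 0` on each affiliated source `s` of
degree `n(s)`. Source quality degrades linearly with total pressure
`p(s) = Σ_a q(a,s)`:

    b(s) = α − β(s) p(s),

and agent payoff includes a quadratic cost for diminishing marginal
utility (coefficient `γ ≥ 0`):

    f(a) = Σ_s q(a,s) b(s) − (γ/2) [Σ_s q(a,s)]².

Two capacity scenarios: *uniform* (`β(s) ≡ β`) and *degree-proportional*
(`β(s) = β₀⟨n⟩/n(s)`, degradation per effort-per-user).

The package computes three distinguished states per network:

* **Nash equilibrium** — unique maximizer of the game's exact concave
  potential over `q ≥ 0`; solved exactly by Cholesky + nonnegative least
  squares and verified against the per-edge complementarity conditions.
* **Pareto efficient state** — maximizer of collective wealth
  `F = Σ_a f(a)` (minimum-norm allocation at `γ = 0`).
* **Reallocation steady state** — fixed point of the myopic flow
  `dq(a,s)/dt = k Σ_{s'∈S_a} [b(s) − b(s')]`, which conserves each agent's
  total effort while shifting it toward higher-quality sources. Computed
  either by integrating the (projected) flow or directly as a linear
  complementarity problem; a Cauchy–Schwarz argument guarantees the
  reallocation never reduces cost-free collective wealth.

A heterogeneous mean-field module predicts degree-class expectations
(`⟨p⟩_n`, `⟨q⟩_{m,n}`, payoff shifts `Δ⟨f⟩_m`), collective wealth and Gini
summaries from the degree distributions `P_A(m)`, `P_S(n)` alone, and a
generator module draws the canonical 9 network ensembles (source families
D/N/PL × agent families U/R/SF at `M = N = 50`, mean degrees 5).

## Worked example

```python
import numpy as np
from cprnet import (
    EnsembleSpec, GameParams, generate_network,
    nash_equilibrium, pareto_efficient, steady_state_lcp,
    collective_wealth, gini, payoffs,
)
from cprnet.netgen import ensemble_rng

spec = EnsembleSpec(source_dist="PL", agent_dist="R", M=50, N=50,
                    mean_m=5, mean_n=5, n_realizations=1, seed=0)
net = generate_network(spec, ensemble_rng(spec, 0))
params = GameParams(alpha=1.0, beta=1.0, gamma=0.2)

eq = nash_equilibrium(net, params)
ss = steady_state_lcp(net, params, eq.state)
ef = pareto_efficient(net, params)

F_eq, F_ss, F_ef = (collective_wealth(r.state, params) for r in (eq, ss, ef))
print(f"collective wealth: Nash {F_eq:.3f} <= steady {F_ss:.3f} <= efficient {F_ef:.3f}")
print(f"price of anarchy F_Eq/F_Ef = {F_eq/F_ef:.3f}")
print(f"Gini: Nash {gini(payoffs(eq.state, params)):.3f} -> steady {gini(payoffs(ss.state, params)):.3f}")
```

prints

```
collective wealth: Nash 9.046 <= steady 10.144 <= efficient 11.174
price of anarchy F_Eq/F_Ef = 0.810
Gini: Nash 0.425 -> steady 0.273
```

On this power-law-source network, rational extraction realizes 81% of the
attainable collective wealth; pure reallocation — no agent changes its
total effort — recovers roughly half of the shortfall and substantially
reduces payoff inequality across agents.

A `cprnet` command-line tool wraps the library for shell use:
`cprnet generate`, `cprnet solve`, `cprnet simulate`, `cprnet meanfield`,
`cprnet sweep`, `cprnet report` (see `--help` on each).

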