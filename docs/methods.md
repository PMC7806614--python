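# Methods

## Model

A static bipartite network connects `M` agents to `N` common-pool sources.
Agent `a` chooses a nonnegative effort `q(a,s)` on each affiliated source;
writing `p(s)` for the total pressure on `s` and `T(a)` for the agent's
total effort, source quality is linear, `b(s) = α − β(s) p(s)`, and payoff
is `f(a) = Σ_s q(a,s) b(s) − (γ/2) T(a)²`. Quality is deliberately not
floored at zero: the equilibrium and steady-state characterizations are
complementarity conditions on the *unclipped* linear form, and clipping
would destroy their uniqueness structure. Collective wealth is
`F = Σ_a f(a)`; the "cost-free" convention `F₀ = Σ_s p(s) b(s)` drops the
quadratic costs, which reallocation cannot change.

Model assumptions: linear degradation, quadratic (agent-level) cost,
exogenous static network, no transfers or exclusion, simultaneous
continuous-time adaptation.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `α` | benefit/effort at zero pressure | 1.0 | sets the payoff scale |
| `β` | degradation slope (uniform scenario) | 1.0 | `β(s) ≡ β` |
| `β₀` | base slope (degree-proportional) | 1.0 | `β(s) = β₀⟨n⟩/n(s)` |
| `γ` | diminishing-marginal-utility coefficient | 0.0 | study range `[0, 1]` |
| `k` | reallocation rate constant | 1.0 | pure time scale; fixed points are k-invariant |

All canonical experiments use `α = β = 1`, so efforts, pressures, and
qualities are dimensionless numbers of order one.

## Distinguished states

**Nash equilibrium.** The game admits an exact potential whose gradient
along each edge equals that agent's marginal payoff
`α − β(s)(p(s) + q(a,s)) − γT(a)`. The potential is strictly concave
(its Hessian is the source-coupling Gram matrix plus a positive diagonal),
so the equilibrium is unique and equals the potential's maximizer over the
nonnegative orthant. We factor the Hessian by Cholesky and solve the
bound-constrained problem with NNLS — an exact active-set method, so the
reported complementarity residuals are at machine precision (~1e-14)
rather than at an iterative tolerance. Solver reports carry the residual;
`converged` means residual ≤ 1e-9. An independent round-robin
best-response iteration (each agent's subproblem is a small strictly
concave QP) is kept as a test oracle.

**Pareto efficient state.** Maximizes `F` directly, same machinery. At
`γ = 0` the welfare Hessian is singular in the allocation directions
(only source pressures matter), so the maximizer is a face, not a point;
we return the minimum-Euclidean-norm point via a Tikhonov ridge of
`1e-10·mean(β)` — the ridge path limit is exactly the min-norm optimizer,
and the KKT residual is always evaluated against the *unridged* program.
Equal splitting among a source's users is the visible consequence.

**Reallocation steady state.** Under the myopic flow each agent conserves
`T(a)`, and stationarity means no agent still sees a quality gradient it
can exploit: every source it actively uses sits at its maximal affiliated
quality `μ(a)`, a linear complementarity problem. It is equivalently the
maximizer of `Σ_s [αp(s) − β(s)p(s)²/2]` over the product of per-agent
scaled simplices; we solve it by FISTA with adaptive restart and a
vectorized grouped simplex projection, stopping when the complementarity
residual `max_e min(q_e, μ(a) − b(s))` falls below 1e-11 (iteration cap
2·10⁵; typical instances converge in a few hundred iterations).

The source pressures of the steady state are unique, but the per-edge
allocation is not: agents sharing equal-quality sources can trade effort
without changing anything observable. All cross-checks between the LCP
solver and the dynamics therefore compare pressures and qualities, never
raw `q`.

## Reallocation dynamics

The flow `dq(a,s)/dt = k Σ_{s'∈S_a} [b(s) − b(s')]` is integrated by
explicit Euler with projected steps: after each raw step the state is
projected back onto each agent's simplex `{q ≥ 0, Σ = T(a)}`. In the
interior this is exactly Euler on the raw rule; at the boundary the fixed
points of the projected step coincide with the LCP steady states. An
earlier variant that merely rescaled inflows when outflow edges hit zero
could freeze an agent in a non-stationary state; the simplex projection
has no such spurious fixed points. Totals are conserved by construction
(and multiplicatively renormalized every 1000 steps to remove accumulated
round-off, keeping worst-case drift below 1e-10).

Step size: the conservative default is `dt = 0.01/(k·maxβ·max m)`; the
`adaptive` scheme instead estimates the spectral radius ρ of the
linearized flow by power iteration and uses `dt = 1/ρ` (Euler is stable
below `2/ρ`; the spectrum is real and nonpositive because the Jacobian is
a product of a per-agent Laplacian-like block and the symmetric source
coupling). The adaptive step is typically 10–100× larger at identical
accuracy of the *limit point*; trajectory-accuracy tests use small fixed
steps.

**Convergence criterion.** Runs are declared converged when the
complementarity residual drops below `tol` (default 1e-8), *not* when the
within-agent quality spread does: at a pinned steady state an agent that
has fully abandoned a degraded source keeps a permanent quality gap, so a
spread criterion never triggers even though the state is exactly
stationary. The spread is still recorded in the trace as a diagnostic.

**Convergence-time comparisons** across agent-degree families (U/R/SF at
fixed source family) are run at `γ = 0` with `k` and `dt` held fixed
across ensembles (`dt` = half the tightest spectral bound over all
networks compared). At cost-free extraction the hub mechanism — a
high-degree agent equalizes many sources simultaneously — dominates and
the mean convergence time orders SF < R < U robustly under every measure
we tried (max residual, rms within-agent gap, wealth gap to the steady
value). At `γ = 0.2` the picture inverts: hubs then hold large totals,
pin many edges at zero, and crawl along boundary faces, making SF
ensembles the *slowest*. The package exposes both regimes; the headline
ordering refers to cost-free extraction.

## Heterogeneous mean field

Nodes are binned by degree and the equilibrium conditions are closed with
the degree distributions assuming no degree-degree correlations. The
linear system for the expected pressures `⟨p⟩_n` couples its unknowns only
through the edge-weighted moment `u = Σ_n P_S(n)(n/⟨n⟩)⟨p⟩_n`, so a scalar
linear equation solves it; the full dense solve is retained and must agree
to 1e-10 (tested). At `γ = 0` the closed form `⟨p⟩_n = (α/βₙ)·n/(n+1)` is
*exact per network* (every edge is active and all users of a source
extract equally), which the per-network solver tests confirm; regular
(D-U) networks make the mean field exact at every `γ` by symmetry.

The payoff shift from equilibrium to steady state is computed from first
principles, `Δ⟨f⟩_m = ⟨T⟩_m·b_f − m·Σ_n w_n ⟨q⟩_{m,n} b_n` (quadratic
costs cancel since totals are conserved); this is the form whose aggregate
reproduces `F_SS = Q·b_f` exactly. A second, closed-form variant with
bracket `⟨n/βₙ⟩ − ⟨n bₙ²/βₙ⟩` in the cost term circulates in the
literature but is dimensionally inconsistent; both are exposed
(`form="first_principles"` / `form="printed"`), they coincide at `γ = 0`,
and discrepancies at `γ > 0` are reported rather than reconciled.

Mean-field summaries: `F_Eq` from the degree-class expected payoffs;
`F_Ef` from a scalar concave program (efficiency requires one common
quality and one common per-agent total, and edge balance removes one
variable, giving `b* = α(1+c)/(2+c)` with `c = γN⟨β⁻¹⟩/M`); Gini indices
over the degree-class payoff distribution weighted by `P_A(m)` —
within-class variance is invisible at this level, so simulated Gini shifts
(computed over individual agents) are systematically at least as large as
the mean-field ones. Steady-state quality `b_f = α − ⟨p⟩/⟨β⁻¹⟩` is applied
per connected component in the network-level code, since reallocation
cannot move effort between components.

The location of the peak mean-field Gini reduction is aggregated as the
mean of per-ensemble argmaxes over the ensembles whose curve is
numerically nonzero (the six with heterogeneous sources; delta-source
ensembles predict identically zero shifts).

## Network generation

Two-stage: degree sequences per side, then a simple bipartite graph.

* `D`/`U`: constant degree `round(mean)`.
* `N`: `round(Normal(mean, σ=1.5))` truncated to `[1, size−1]`.
* `PL`/`SF`: discrete power law `p(d) ∝ d^(−τ)` on `[1, size−1]` with τ
  solved numerically (Brent) so the truncated mean equals the target.
* `R`: multinomial occupancy of the exact edge total over nodes
  (binomial-like margins), zero bins repaired from degree ≥ 2 nodes.

Stochastic families are redrawn (bounded) until the sample mean is within
5% of target — the ensembles are *defined* by their shared mean degree, and
a heavy-tailed draw of 50 degrees misses 5% most of the time otherwise.
Unequal stub totals are reconciled by ±1 adjustments at random nodes,
preferentially on the agent side so that the realized source-degree
marginal stays within its sampled family (ensembles sharing a source
family must be statistically indistinguishable in `P_S`; tested by a
chi-square two-sample test). Graphs are realized by configuration-model
stub pairing with duplicate edges removed by random double-edge swaps;
heavy-tailed sequences that resist random repair fall back to a greedy
Gale–Ryser-feasible construction followed by `10·E` randomizing swaps.
Degree-sequence pairs that are not bigraphical are rejected, redrawing only
the agent sequence so the source marginal stays unconditioned on
feasibility. No degree-degree correlation is imposed, matching the
mean-field ansatz.

**What the generator emulates and what it does not.** It reproduces the
family shapes, the shared mean degree 5, and the shared-source-marginal
property of the canonical ensembles. It does not reproduce any particular
published construction for "scale-free-type" sequences, and the
truncation/repair steps introduce mild finite-size corrections (e.g.
slight agent-degree spread in nominally uniform ensembles after
reconciliation). Passing tests therefore validate the *model pipeline* on
networks with these statistical features, not any claim about empirical
CPR networks, which have correlations, weights, and dynamics this model
excludes by assumption.

## Numerical choices and degenerate inputs

* KKT/complementarity tolerances: Nash 1e-9, Pareto 1e-8, LCP 1e-11,
  dynamics 1e-8 — all on the `α = β = 1` scale and configurable.
* Gini is undefined (raises) when payoffs sum to ≤ 0, and warns when any
  payoff is negative; in the parameter ranges studied equilibrium payoffs
  are nonnegative.
* Degrees with zero mass are excluded from the mean-field system;
  mean-field-negative `⟨q⟩_{m,n}` predictions are retained but flagged
  with a warning (they mark where the uncorrelated closure degrades).
* Agents with a single source are trivially stationary; empty networks and
  isolated nodes are rejected at construction.
* Seeding: a master seed spawns per-(ensemble, realization) children via
  `SeedSequence(master, spawn_key=(ensemble_index, realization))`, so any
  subset of a design reproduces bit-for-bit.

## Problem sizes

The test suite and the reproduction script run the canonical geometry
(`M = N = 50`, mean degrees 5) at 100 realizations per ensemble — the
package's desk-scale default, chosen so a full 9-ensemble study completes
in about a minute on one core; `n_realizations` scales to the full 10³ for
production runs. Property tests use random networks of 3–50 nodes per
side.

## Known limitations

* The uncorrelated mean field degrades when *both* sides are heavy-tailed:
  at `γ = 0.2` the ensemble-mean pressures on PL-SF networks deviate from
  the prediction by up to ~35% at rare degrees (single-heavy-tailed
  ensembles stay within ~5%). Simulated reallocation shifts are
  correspondingly larger than predicted ones.
* Pareto and steady-state allocations are non-unique at `γ = 0` /
  equal-quality faces; only pressures and qualities are contract-stable.
* The dynamics integrator is first-order; trajectory-pointwise accuracy is
  `O(dt)` even though limit points are solver-exact.
* No weighted, directed, evolving, or degree-correlated networks; no
  nonlinear degradation; no per-agent heterogeneous `α`, `γ`.
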