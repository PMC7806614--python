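"""Heterogeneous mean-field predictions from degree distributions alone.

Nodes are binned by degree and the Nash-equilibrium conditions are closed
with the degree distributions ``P_A(m)``, ``P_S(n)`` assuming no
degree-degree correlations.  The unknown expected pressures on degree-n
sources, ``<q->_n``, satisfy one linear condition per source degree; the
system couples the unknowns only through the edge-weighted moment

    u = sum_n P_S(n) (n/<n>) <q->_n,

so it reduces to a single scalar linear equation (the full linear solve is
retained as a cross-check).  From the pressures follow the expected agent
totals ``<q>_m``, per-edge extractions ``<q>_{m,n}``, the equalized
steady-state quality ``b_f``, payoff shifts under reallocation, and the
collective-wealth and Gini summaries behind the gamma-sweep figures.

Notation used below for edge-weighted source averages:
``<x>_e = sum_n P_S(n) (n/<n>) x_n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import GameParams, weighted_gini
from .netgen import DegreeDistributions

__all__ = [
    "MeanFieldSolution",
    "resolve_beta_n",
    "solve_equilibrium_pressures",
    "agent_totals",
    "edge_extractions",
    "payoff_shifts",
    "summarize",
    "solve",
    "gamma_sweep",
    "gini_reduction_peak",
]


def _arrays(dists: DegreeDistributions):
    ns = np.array(sorted(dists.P_S), dtype=float)
    ps = np.array([dists.P_S[int(n)] for n in ns])
    ms = np.array(sorted(dists.P_A), dtype=float)
    pa = np.array([dists.P_A[int(m)] for m in ms])
    return ns, ps, ms, pa


def resolve_beta_n(dists: DegreeDistributions, params: GameParams) -> dict[int, float]:
    """Degradation slope by source degree, ``beta_n``, under the capacity scenario."""
    ns, _, _, _ = _arrays(dists)
    if params.scenario == "uniform":
        vals = np.full(ns.size, params.beta)
    else:
        vals = params.beta0 * dists.mean_n / ns
    return {int(n): float(v) for n, v in zip(ns, vals)}


def _core(dists: DegreeDistributions, params: GameParams):
    """Shared moments: edge weights w_n, beta_n, B1=<1/beta>_e, and the
    agent-side coefficient C = sum_m P_A(m)(m/<m>) * gamma*m/(gamma*m*B1+1)."""
    ns, ps, ms, pa = _arrays(dists)
    beta_n = np.array([resolve_beta_n(dists, params)[int(n)] for n in ns])
    w_n = ps * ns / dists.mean_n
    B1 = float(w_n @ (1.0 / beta_n))
    g = params.gamma
    C = float((pa * ms / dists.mean_m) @ (g * ms / (g * ms * B1 + 1.0)))
    return ns, ps, ms, pa, beta_n, w_n, B1, C


def solve_equilibrium_pressures(
    dists: DegreeDistributions, params: GameParams, method: str = "scalar"
) -> dict[int, float]:
    """Expected Nash pressure ``<q->_n`` on sources of each degree.

    ``method="scalar"`` exploits that the system depends on the unknowns only
    through the edge-weighted moment ``u``; ``method="full"`` assembles and
    solves the dense linear system over all source degrees with mass.  The
    two agree to machine precision (an invariant under test).
    """
    ns, ps, ms, pa, beta_n, w_n, B1, C = _core(dists, params)
    a = params.alpha
    coef = (ns / (ns + 1.0)) / beta_n  # per-degree prefactor of [alpha - C(alpha*B1 - u)]
    if method == "scalar":
        K = float(w_n @ coef)
        denom = 1.0 - K * C
        if abs(denom) < 1e-14:
            raise ValueError("mean-field system is singular for these parameters")
        u = a * K * (1.0 - C * B1) / denom
        qn = coef * (a - C * (a * B1 - u))
    elif method == "full":
        k = ns.size
        A = np.eye(k) - np.outer(coef * C, w_n)
        rhs = coef * a * (1.0 - C * B1)
        if abs(np.linalg.det(A)) < 1e-14:
            raise ValueError("mean-field system is singular for these parameters")
        qn = np.linalg.solve(A, rhs)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {int(n): float(q) for n, q in zip(ns, qn)}


def agent_totals(
    dists: DegreeDistributions, params: GameParams, qn: dict[int, float]
) -> dict[int, float]:
    """Expected equilibrium total extraction ``<q<-_m`` of a degree-m agent."""
    ns, ps, ms, pa, beta_n, w_n, B1, _ = _core(dists, params)
    u = float(w_n @ np.array([qn[int(n)] for n in ns]))
    g = params.gamma
    qm = (ms / (ms * g * B1 + 1.0)) * (params.alpha * B1 - u)
    return {int(m): float(v) for m, v in zip(ms, qm)}


def edge_extractions(
    dists: DegreeDistributions,
    params: GameParams,
    qn: dict[int, float],
    qm: dict[int, float],
) -> dict[tuple[int, int], float]:
    """Expected equilibrium per-edge extraction ``<q>_{m,n}``.

    The mean-field closure can predict negative values for extreme degree
    pairs (the approximation degrading); these are kept but flagged with a
    warning.
    """
    ns, ps, ms, pa, beta_n, w_n, B1, _ = _core(dists, params)
    out: dict[tuple[int, int], float] = {}
    neg = 0
    for m in ms:
        for n, bn in zip(ns, beta_n):
            v = params.alpha / bn - qn[int(n)] - (params.gamma / bn) * qm[int(m)]
            if v < 0:
                neg += 1
            out[(int(m), int(n))] = float(v)
    if neg:
        warnings.warn(
            f"mean field predicts negative edge extraction for {neg} (m,n) pairs",
            stacklevel=2,
        )
    return out


def _qualities(dists, params, qn):
    ns, ps, ms, pa, beta_n, w_n, B1, _ = _core(dists, params)
    qn_arr = np.array([qn[int(n)] for n in ns])
    bn = params.alpha - beta_n * qn_arr
    mean_pressure = float(ps @ qn_arr)
    mean_inv_beta = float(ps @ (1.0 / beta_n))
    b_f = params.alpha - mean_pressure / mean_inv_beta
    return ns, ps, ms, pa, beta_n, w_n, bn, b_f


def payoff_shifts(
    dists: DegreeDistributions,
    params: GameParams,
    qn: dict[int, float],
    qm: dict[int, float],
    form: str = "first_principles",
) -> dict[int, float]:
    """Expected payoff change ``Delta<f>_m`` from equilibrium to steady state.

    ``form="first_principles"`` evaluates the difference of expected payoffs
    directly (quadratic costs cancel because totals are conserved):

        Delta<f>_m = <q<-_m * b_f - m * <q_{m,n} * b_n>_e.

    ``form="printed"`` evaluates the closed-form expression with second
    bracket ``<n/beta_n> - <n b_n^2/beta_n>``; the two coincide at gamma=0
    but differ for gamma>0 (that bracket is dimensionally inconsistent, and
    the first-principles form is the one that reproduces F_SS = Q*b_f).
    Both are exposed so discrepancies are visible rather than reconciled
    silently.
    """
    ns, ps, ms, pa, beta_n, w_n, bn, b_f = _qualities(dists, params, qn)
    g = params.gamma
    e_b_over_beta = float(w_n @ (bn / beta_n))
    e_b2_over_beta = float(w_n @ (bn**2 / beta_n))
    e_inv_beta = float(w_n @ (1.0 / beta_n))
    out: dict[int, float] = {}
    for m in ms:
        qm_m = qm[int(m)]
        if form == "first_principles":
            bracket2 = e_inv_beta * b_f - e_b_over_beta
        elif form == "printed":
            bracket2 = e_inv_beta - e_b2_over_beta
        else:
            raise ValueError(f"unknown form {form!r}")
        out[int(m)] = float(m * ((e_b_over_beta * b_f - e_b2_over_beta) - g * qm_m * bracket2))
    return out


@dataclass(frozen=True)
class MeanFieldSolution:
    """Degree-indexed expectations and scalar summaries for one parameter set."""

    params: GameParams
    qn: dict[int, float]
    qm: dict[int, float]
    qmn: dict[tuple[int, int], float]
    bn: dict[int, float]
    b_f: float
    delta_f: dict[int, float]
    delta_f_printed: dict[int, float]
    f_eq_by_m: dict[int, float]
    f_ss_by_m: dict[int, float]
    F_Eq: float
    F_SS: float
    F_Ef: float
    G_Eq: float
    G_SS: float


def _efficient_wealth(
    dists: DegreeDistributions, params: GameParams, M: int, N: int
) -> float:
    """Mean-field Pareto-efficient collective wealth.

    Efficiency requires one common quality b* across sources and one common
    total T across agents; edge balance fixes T = N(alpha-b*)<1/beta>/M,
    leaving a scalar concave program in b* solved in closed form.
    """
    ns, ps, *_ = _arrays(dists)
    beta_n = np.array([resolve_beta_n(dists, params)[int(n)] for n in ns])
    inv_beta = float(ps @ (1.0 / beta_n))
    a, g = params.alpha, params.gamma
    c = g * N * inv_beta / M
    b_star = a * (1.0 + c) / (2.0 + c)
    Q = N * (a - b_star) * inv_beta
    return float(Q * b_star - 0.5 * g * Q * Q / M)


def summarize(
    dists: DegreeDistributions,
    params: GameParams,
    qn: dict[int, float],
    qm: dict[int, float],
    qmn: dict[tuple[int, int], float],
    delta_f: dict[int, float],
    M: int = 50,
    N: int = 50,
):
    """Collective wealth (costs included) and degree-class Gini at
    equilibrium and steady state, plus the efficient benchmark.

    The Gini is over the degree-class payoff distribution {<f>_m with mass
    P_A(m)} — within-class variance is invisible to the mean field.
    """
    ns, ps, ms, pa, beta_n, w_n, bn, b_f = _qualities(dists, params, qn)
    g = params.gamma
    f_eq, f_ss = {}, {}
    for m in ms:
        m_i = int(m)
        # expected benefit: m * sum_n w_n <q>_{m,n} b_n
        benefit = m * float(w_n @ (np.array([qmn[(m_i, int(n))] for n in ns]) * bn))
        cost = 0.5 * g * qm[m_i] ** 2
        f_eq[m_i] = benefit - cost
        f_ss[m_i] = f_eq[m_i] + delta_f[m_i]
    F_Eq = M * float(pa @ np.array([f_eq[int(m)] for m in ms]))
    F_SS = M * float(pa @ np.array([f_ss[int(m)] for m in ms]))
    F_Ef = _efficient_wealth(dists, params, M, N)
    G_Eq = weighted_gini(np.array([f_eq[int(m)] for m in ms]), pa)
    G_SS = weighted_gini(np.array([f_ss[int(m)] for m in ms]), pa)
    return F_Eq, F_SS, F_Ef, G_Eq, G_SS, f_eq, f_ss


def solve(
    dists: DegreeDistributions, params: GameParams, M: int = 50, N: int = 50
) -> MeanFieldSolution:
    """Full mean-field solution for one parameter set."""
    qn = solve_equilibrium_pressures(dists, params)
    qm = agent_totals(dists, params, qn)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qmn = edge_extractions(dists, params, qn, qm)
    delta_f = payoff_shifts(dists, params, qn, qm, form="first_principles")
    delta_f_printed = payoff_shifts(dists, params, qn, qm, form="printed")
    F_Eq, F_SS, F_Ef, G_Eq, G_SS, f_eq, f_ss = summarize(
        dists, params, qn, qm, qmn, delta_f, M=M, N=N
    )
    ns, ps, ms, pa, beta_n, w_n, bn, b_f = _qualities(dists, params, qn)
    return MeanFieldSolution(
        params=params,
        qn=qn,
        qm=qm,
        qmn=qmn,
        bn={int(n): float(b) for n, b in zip(ns, bn)},
        b_f=float(b_f),
        delta_f=delta_f,
        delta_f_printed=delta_f_printed,
        f_eq_by_m=f_eq,
        f_ss_by_m=f_ss,
        F_Eq=F_Eq,
        F_SS=F_SS,
        F_Ef=F_Ef,
        G_Eq=G_Eq,
        G_SS=G_SS,
    )


def gini_reduction_peak(
    dists_by_label: dict[str, DegreeDistributions],
    params_template: GameParams,
    gamma_grid,
    M: int = 50,
    N: int = 50,
    min_peak: float = 1e-6,
) -> tuple[float, dict[str, float]]:
    """Location of the maximal predicted Gini reduction, per ensemble.

    For each ensemble's degree distributions, sweeps gamma and finds the
    argmax of ``G_Eq - G_SS``.  Ensembles whose curve never rises above
    ``min_peak`` (homogeneous sources predict no shift at all) are left
    out of the aggregate.  Returns ``(mean argmax over qualifying
    ensembles, per-ensemble argmax dict)``.
    """
    grid = np.asarray(list(gamma_grid), dtype=float)
    peaks: dict[str, float] = {}
    for label, dists in dists_by_label.items():
        df = gamma_sweep(dists, params_template, grid, M=M, N=N)
        drops = df["G_drop"].to_numpy()
        if drops.max() > min_peak:
            peaks[label] = float(grid[int(np.argmax(drops))])
    if not peaks:
        raise ValueError("no ensemble shows a nonzero Gini-reduction peak")
    return float(np.mean(list(peaks.values()))), peaks


def gamma_sweep(
    dists: DegreeDistributions,
    params_template: GameParams,
    gamma_grid,
    M: int = 50,
    N: int = 50,
) -> pd.DataFrame:
    """Sweep the cost parameter: one row per gamma with the figure-style
    summaries ``F_Eq/F_Ef``, ``(F_SS-F_Eq)/F_Ef``, ``G_Eq``, ``G_Eq-G_SS``."""
    rows = []
    for g in gamma_grid:
        if g < 0:
            raise ValueError("gamma must be >= 0")
        sol = solve(dists, params_template.with_gamma(float(g)), M=M, N=N)
        rows.append(
            {
                "gamma": float(g),
                "F_Eq": sol.F_Eq,
                "F_SS": sol.F_SS,
                "F_Ef": sol.F_Ef,
                "F_Eq_over_F_Ef": sol.F_Eq / sol.F_Ef,
                "gain_over_F_Ef": (sol.F_SS - sol.F_Eq) / sol.F_Ef,
                "G_Eq": sol.G_Eq,
                "G_drop": sol.G_Eq - sol.G_SS,
            }
        )
    return pd.DataFrame(rows)
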