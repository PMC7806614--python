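"""Heterogeneous mean-field solutions against closed forms and simulations."""

import numpy as np
import pytest

from cprnet import meanfield as mf
from cprnet.game import GameParams
from cprnet.netgen import DegreeDistributions, build_bipartite
from cprnet.solvers import nash_equilibrium


def rng(seed=0):
    return np.random.Generator(np.random.PCG64(seed))


DELTA = DegreeDistributions(P_A={5: 1.0}, P_S={5: 1.0})
MIXED = DegreeDistributions(
    P_A={2: 0.3, 5: 0.4, 9: 0.3}, P_S={3: 0.5, 6: 0.3, 10: 0.2}
)


class TestEquilibriumPressures:
    @pytest.mark.parametrize("dists", [DELTA, MIXED])
    def test_gamma0_closed_form(self, dists):
        p = GameParams(gamma=0.0)
        qn = mf.solve_equilibrium_pressures(dists, p)
        for n, v in qn.items():
            assert v == pytest.approx(n / (n + 1), abs=1e-12)

    @pytest.mark.parametrize("gamma", [0.0, 0.2, 1.0])
    @pytest.mark.parametrize("scenario", ["uniform", "degree_proportional"])
    def test_scalar_and_full_solve_agree(self, gamma, scenario):
        p = GameParams(gamma=gamma, scenario=scenario)
        qs = mf.solve_equilibrium_pressures(MIXED, p, method="scalar")
        qf = mf.solve_equilibrium_pressures(MIXED, p, method="full")
        for n in qs:
            assert qs[n] == pytest.approx(qf[n], abs=1e-10)

    def test_alpha_scaling(self):
        p = GameParams(alpha=2.0, gamma=0.3)
        p1 = GameParams(alpha=1.0, gamma=0.3)
        q2 = mf.solve_equilibrium_pressures(MIXED, p)
        q1 = mf.solve_equilibrium_pressures(MIXED, p1)
        for n in q1:
            assert q2[n] == pytest.approx(2 * q1[n], abs=1e-12)

    @pytest.mark.parametrize("gamma", [0.0, 0.2, 0.7])
    def test_exact_on_regular_network(self, gamma):
        # on a 5-regular bipartite graph the symmetric Nash state makes the
        # mean field exact for every gamma
        net = build_bipartite([5] * 30, [5] * 30, rng(1))
        p = GameParams(gamma=gamma)
        rep = nash_equilibrium(net, p)
        qn = mf.solve_equilibrium_pressures(DELTA, p)
        np.testing.assert_allclose(rep.state.source_pressures, qn[5], atol=1e-8)


class TestAgentTotals:
    def test_delta_case_value(self):
        p = GameParams(gamma=0.0)
        qn = mf.solve_equilibrium_pressures(DELTA, p)
        qm = mf.agent_totals(DELTA, p, qn)
        assert qm[5] == pytest.approx(5 / 6, abs=1e-12)

    def test_infinite_cost_suppresses_extraction(self):
        p = GameParams(gamma=1e9)
        qn = mf.solve_equilibrium_pressures(MIXED, p)
        qm = mf.agent_totals(MIXED, p, qn)
        assert all(abs(v) < 1e-6 for v in qm.values())

    def test_edge_balance(self):
        p = GameParams(gamma=0.4)
        qn = mf.solve_equilibrium_pressures(MIXED, p)
        qm = mf.agent_totals(MIXED, p, qn)
        M = 50
        N = M * MIXED.mean_m / MIXED.mean_n
        via_agents = M * sum(MIXED.P_A[m] * qm[m] for m in qm)
        via_sources = N * sum(MIXED.P_S[n] * qn[n] for n in qn)
        assert via_agents == pytest.approx(via_sources, abs=1e-10)


class TestEdgeExtractions:
    def test_gamma0_independent_of_agent_degree(self):
        p = GameParams(gamma=0.0)
        qn = mf.solve_equilibrium_pressures(DELTA, p)
        qm = mf.agent_totals(DELTA, p, qn)
        qmn = mf.edge_extractions(DELTA, p, qn, qm)
        assert qmn[(5, 5)] == pytest.approx(1 / 6, abs=1e-12)

    def test_consistency_identity_with_totals(self):
        # m * sum_n w_n <q>_{m,n} == <q>_m
        p = GameParams(gamma=0.6)
        qn = mf.solve_equilibrium_pressures(MIXED, p)
        qm = mf.agent_totals(MIXED, p, qn)
        qmn = mf.edge_extractions(MIXED, p, qn, qm)
        mean_n = MIXED.mean_n
        for m in qm:
            acc = sum(
                MIXED.P_S[n] * n / mean_n * qmn[(m, n)] for n in sorted(MIXED.P_S)
            )
            assert m * acc == pytest.approx(qm[m], abs=1e-10)


class TestPayoffShifts:
    def test_gamma0_shifts_proportional_to_degree(self):
        p = GameParams(gamma=0.0)
        qn = mf.solve_equilibrium_pressures(MIXED, p)
        qm = mf.agent_totals(MIXED, p, qn)
        df = mf.payoff_shifts(MIXED, p, qn, qm)
        per_edge = {m: v / m for m, v in df.items()}
        vals = list(per_edge.values())
        assert max(vals) - min(vals) < 1e-12
        assert vals[0] > 0  # heterogeneous sources: strict gain

    def test_delta_sources_predict_no_shift(self):
        p = GameParams(gamma=0.4)
        d = DegreeDistributions(P_A=MIXED.P_A, P_S={5: 1.0})
        qn = mf.solve_equilibrium_pressures(d, p)
        qm = mf.agent_totals(d, p, qn)
        df = mf.payoff_shifts(d, p, qn, qm)
        assert all(abs(v) < 1e-12 for v in df.values())

    def test_printed_form_agrees_at_gamma0_only(self):
        p0 = GameParams(gamma=0.0)
        qn = mf.solve_equilibrium_pressures(MIXED, p0)
        qm = mf.agent_totals(MIXED, p0, qn)
        fp = mf.payoff_shifts(MIXED, p0, qn, qm, form="first_principles")
        pr = mf.payoff_shifts(MIXED, p0, qn, qm, form="printed")
        for m in fp:
            assert fp[m] == pytest.approx(pr[m], abs=1e-12)
        p1 = GameParams(gamma=0.5)
        qn1 = mf.solve_equilibrium_pressures(MIXED, p1)
        qm1 = mf.agent_totals(MIXED, p1, qn1)
        fp1 = mf.payoff_shifts(MIXED, p1, qn1, qm1, form="first_principles")
        pr1 = mf.payoff_shifts(MIXED, p1, qn1, qm1, form="printed")
        assert any(abs(fp1[m] - pr1[m]) > 1e-6 for m in fp1)

    def test_first_principles_shift_reproduces_steady_wealth(self):
        # F_SS (cost-free part) must equal Q * b_f
        p = GameParams(gamma=0.5)
        sol = mf.solve(MIXED, p, M=50, N=50)
        M = 50
        Q = M * sum(MIXED.P_A[m] * sol.qm[m] for m in sol.qm)
        F_ss_costfree = M * sum(
            MIXED.P_A[m] * (sol.f_ss_by_m[m] + 0.5 * p.gamma * sol.qm[m] ** 2)
            for m in sol.qm
        )
        assert F_ss_costfree == pytest.approx(Q * sol.b_f, abs=1e-9)


class TestSummaries:
    def test_delta_delta_wealth_values(self):
        sol = mf.solve(DELTA, GameParams(gamma=0.0), M=50, N=50)
        assert sol.F_Eq == pytest.approx(50 * 5 / 36, abs=1e-9)
        assert sol.F_Ef == pytest.approx(12.5, abs=1e-9)
        assert sol.F_Eq / sol.F_Ef == pytest.approx(5 / 9, abs=1e-9)
        assert sol.G_Eq == 0.0  # single agent class

    def test_gamma0_gini_unchanged_by_reallocation(self):
        sol = mf.solve(MIXED, GameParams(gamma=0.0))
        assert sol.G_Eq == pytest.approx(sol.G_SS, abs=1e-12)

    def test_gamma_sweep_layout_and_gamma0_row(self):
        df = mf.gamma_sweep(MIXED, GameParams(), [0.0, 0.2, 0.5])
        assert list(df["gamma"]) == [0.0, 0.2, 0.5]
        assert df.loc[0, "G_drop"] == pytest.approx(0.0, abs=1e-12)
        assert (df["F_Eq_over_F_Ef"] <= 1 + 1e-12).all()
        # efficiency ratio improves as diminishing returns temper extraction
        assert df["F_Eq_over_F_Ef"].is_monotonic_increasing

    def test_heterogeneous_sources_reduce_gini_at_positive_gamma(self):
        sol = mf.solve(MIXED, GameParams(gamma=0.2))
        assert sol.G_Eq - sol.G_SS > 0

    def test_sweep_rejects_negative_gamma(self):
        with pytest.raises(ValueError):
            mf.gamma_sweep(MIXED, GameParams(), [-0.1])


class TestSourceHeterogeneityOrdering:
    def test_reallocation_gain_ranks_pl_above_n_above_d(self, canonical_dists):
        p = GameParams(gamma=0.0)
        gains = {}
        for src in ("D", "N", "PL"):
            d = canonical_dists[f"{src}-R"]
            sol = mf.solve(d, p)
            gains[src] = (sol.F_SS - sol.F_Eq) / sol.F_Ef
        assert gains["PL"] > gains["N"] > gains["D"] - 1e-15

    def test_nash_pressures_within_5pct_of_simulation_at_gamma02(
        self, canonical_ensembles, canonical_dists
    ):
        # substantive check away from the closed-form regime: N-R ensemble
        p = GameParams(gamma=0.2)
        nets = canonical_ensembles["N-R"][:50]
        qn = mf.solve_equilibrium_pressures(canonical_dists["N-R"], p)
        acc: dict[int, list] = {}
        for net in nets:
            pr = nash_equilibrium(net, p).state.source_pressures
            for n in np.unique(net.source_degrees):
                acc.setdefault(int(n), []).extend(pr[net.source_degrees == n].tolist())
        total = sum(len(v) for v in acc.values())
        for n, vals in acc.items():
            if len(vals) < 0.01 * total:
                continue  # too rare for a stable ensemble mean
            sim = float(np.mean(vals))
            assert abs(sim - qn[n]) / qn[n] < 0.05, (n, sim, qn[n])
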