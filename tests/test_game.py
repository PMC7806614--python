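"""Payoffs, collective wealth, Gini, and the reallocation welfare theorem."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cprnet.game import (
    ExtractionState,
    GameParams,
    collective_wealth,
    gini,
    payoffs,
    quality,
    read_state,
    resolve_beta,
    steady_state_quality,
    steady_wealth,
    weighted_gini,
    write_state,
)
from cprnet.network import BipartiteNetwork

from conftest import random_network, random_state


def rng(seed=0):
    return np.random.Generator(np.random.PCG64(seed))


def toy_1x2():
    return BipartiteNetwork.from_edges(1, 2, [(0, 0), (0, 1)])


class TestBetaResolution:
    def test_uniform_scenario(self):
        net = toy_1x2()
        beta = resolve_beta(net, GameParams(beta=1.0))
        assert (beta == 1.0).all()

    def test_degree_proportional_scales_inversely_with_degree(self):
        # 2 sources of degree 5 and 10: mean degree 7.5
        edges = [(a, 0) for a in range(5)] + [(a, 1) for a in range(10)]
        net = BipartiteNetwork.from_edges(10, 2, edges)
        p = GameParams(scenario="degree_proportional", beta0=1.0)
        beta = resolve_beta(net, p)
        mean_n = 7.5
        assert beta[0] == pytest.approx(mean_n / 5)
        assert beta[1] == pytest.approx(mean_n / 10)
        # a source at exactly the mean degree would get beta0; check the ratio
        assert beta[0] / beta[1] == pytest.approx(2.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GameParams(alpha=-1)
        with pytest.raises(ValueError):
            GameParams(gamma=-0.1)
        with pytest.raises(ValueError):
            GameParams(scenario="quadratic")


class TestQualityAndPayoffs:
    def test_pristine_source_has_quality_alpha(self):
        st_ = ExtractionState.zeros(toy_1x2())
        assert quality(st_, GameParams(alpha=1.3)).tolist() == [1.3, 1.3]

    def test_quality_linear_form_and_negativity(self):
        net = toy_1x2()
        st_ = ExtractionState(net, np.array([0.6, 1.5]))
        b = quality(st_, GameParams())
        assert b[0] == pytest.approx(0.4)
        assert b[1] == pytest.approx(-0.5)  # over-exploitation representable

    def test_payoff_hand_values(self):
        net = BipartiteNetwork.from_edges(1, 1, [(0, 0)])
        st_ = ExtractionState(net, np.array([0.5]))
        assert payoffs(st_, GameParams(gamma=0.0))[0] == pytest.approx(0.25)
        assert payoffs(st_, GameParams(gamma=1.0))[0] == pytest.approx(0.125)
        assert payoffs(ExtractionState.zeros(net), GameParams())[0] == 0.0

    def test_collective_wealth_conventions(self):
        net = toy_1x2()
        p = GameParams()
        st0 = ExtractionState(net, np.array([0.6, 0.0]))
        assert collective_wealth(st0, p, include_costs=False) == pytest.approx(0.24)
        st1 = ExtractionState(net, np.array([0.3, 0.3]))
        assert collective_wealth(st1, p, include_costs=False) == pytest.approx(0.42)
        assert collective_wealth(ExtractionState.zeros(net), p) == 0.0
        # with costs: subtract (gamma/2) * total^2
        p2 = GameParams(gamma=1.0)
        assert collective_wealth(st0, p2) == pytest.approx(0.24 - 0.5 * 0.36)

    def test_doubling_efforts_scales_wealth_quadratically(self):
        r = rng(4)
        net = random_network(r)
        st1 = random_state(r, net, scale=0.2)
        st2 = ExtractionState(net, 2 * st1.q)
        p = GameParams()
        a_term = p.alpha * st1.total_extraction
        quad = a_term - collective_wealth(st1, p, include_costs=False)
        assert collective_wealth(st2, p, include_costs=False) == pytest.approx(
            2 * a_term - 4 * quad
        )


class TestGini:
    def test_known_values(self):
        assert gini(np.array([1.0, 1.0, 1.0])) == pytest.approx(0.0)
        assert gini(np.array([0.0, 1.0])) == pytest.approx(0.5)
        assert gini(np.array([1.0, 1.0, 1.0, 0.0])) == pytest.approx(0.25)

    def test_matches_pairwise_definition(self):
        r = rng(1)
        v = r.uniform(0, 2, size=37)
        pairwise = np.abs(v[:, None] - v[None, :]).sum() / (2 * v.size * v.sum())
        assert gini(v) == pytest.approx(pairwise, abs=1e-12)

    def test_undefined_for_nonpositive_total(self):
        with pytest.raises(ValueError, match="undefined"):
            gini(np.array([1.0, -2.0]))

    def test_warns_on_negative_values(self):
        with pytest.warns(UserWarning, match="negative"):
            gini(np.array([-0.1, 2.0]))

    def test_weighted_gini_matches_replicated_sample(self):
        vals = np.array([1.0, 3.0])
        w = np.array([0.25, 0.75])
        sample = np.array([1.0, 3.0, 3.0, 3.0])
        assert weighted_gini(vals, w) == pytest.approx(gini(sample))


class TestSteadyStateQuality:
    def test_uniform_beta_mean_pressure(self):
        net = toy_1x2()
        p = GameParams()
        b_f = steady_state_quality(net, p, np.array([5 / 6, 5 / 6]))
        assert b_f == pytest.approx(1 / 6)

    def test_zero_extraction_gives_alpha(self):
        net = toy_1x2()
        b_f = steady_state_quality(net, GameParams(alpha=2.0), np.zeros(2))
        assert (b_f == 2.0).all()

    def test_two_beta_values(self):
        # degree-proportional scenario yields distinct betas: (1.5, 0.75)
        edges = [(0, 0), (0, 1), (1, 1)]
        net2 = BipartiteNetwork.from_edges(2, 2, edges)
        p2 = GameParams(scenario="degree_proportional", beta0=1.0)
        beta = resolve_beta(net2, p2)  # mean n = 1.5 -> beta = (1.5, 0.75)
        pressures = np.array([0.3, 0.3])
        expected = p2.alpha - 0.6 / (1 / beta[0] + 1 / beta[1])
        got = steady_state_quality(net2, p2, pressures)
        assert got == pytest.approx(expected)

    def test_disconnected_components_equalize_separately(self):
        edges = [(0, 0), (0, 1), (1, 2)]
        net = BipartiteNetwork.from_edges(2, 3, edges)
        p = GameParams()
        b_f = steady_state_quality(net, p, np.array([0.4, 0.0, 0.9]))
        assert b_f[0] == pytest.approx(1 - 0.4 / 2)
        assert b_f[1] == pytest.approx(1 - 0.4 / 2)
        assert b_f[2] == pytest.approx(0.1)


class TestWelfareTheorem:
    """Equalizing qualities while conserving totals never reduces cost-free wealth."""

    @given(seed=st.integers(0, 10_000), scenario=st.sampled_from(["uniform", "degree_proportional"]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_steady_wealth_dominates(self, seed, scenario):
        r = rng(seed)
        net = random_network(r)
        st_ = random_state(r, net)
        p = GameParams(scenario=scenario)
        f0 = collective_wealth(st_, p, include_costs=False)
        ff = steady_wealth(st_, p)
        assert ff >= f0 - 1e-12

    def test_equality_iff_quality_already_uniform(self):
        r = rng(7)
        net = random_network(r, M=6, N=6)
        p = GameParams()
        beta = resolve_beta(net, p)
        # construct an equal-quality state: beta(s) * pressure(s) == const
        target = 0.3 / beta  # beta*pressure = 0.3 everywhere
        q = target[net.source_of_edge] / net.source_degrees[net.source_of_edge]
        st_eq = ExtractionState(net, q)
        assert steady_wealth(st_eq, p) == pytest.approx(
            collective_wealth(st_eq, p, include_costs=False), abs=1e-12
        )
        # non-uniform quality: strict improvement
        st_rand = random_state(r, net)
        b = quality(st_rand, p)
        assert b.std() > 1e-6
        assert steady_wealth(st_rand, p) > collective_wealth(
            st_rand, p, include_costs=False
        ) + 1e-12

    def test_wealth_per_effort_identity(self):
        # F0/Q = alpha - <beta*pressure^2>/<pressure>
        r = rng(9)
        net = random_network(r)
        st_ = random_state(r, net)
        p = GameParams(scenario="degree_proportional")
        beta = resolve_beta(net, p)
        pr = st_.source_pressures
        lhs = collective_wealth(st_, p, include_costs=False) / st_.total_extraction
        rhs = p.alpha - (beta * pr**2).mean() / pr.mean()
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestStateIO:
    def test_roundtrip_preserves_q_exactly(self, tmp_path):
        r = rng(11)
        net = random_network(r)
        st_ = random_state(r, net)
        p = GameParams(gamma=0.3)
        path = tmp_path / "state.tsv"
        write_state(st_, path, p)
        back = read_state(path, net)
        assert (back.q == st_.q).all()
        assert (tmp_path / "state.tsv.json").exists()

    def test_reader_rejects_foreign_edges(self, tmp_path):
        net = toy_1x2()
        path = tmp_path / "state.tsv"
        path.write_text("agent_id\tsource_id\tq\n0\t0\t0.5\n5\t5\t0.1\n")
        with pytest.raises(ValueError, match="not in the network"):
            read_state(path, net)
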