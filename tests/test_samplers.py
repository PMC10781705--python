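import numpy as np
import pytest
from scipy import stats

from walklink import (
    GGMOracle,
    Network,
    build_a2,
    build_a3,
    draw_a2,
    draw_a3,
    exact_power_distribution,
    generate_er,
    query_cost_report,
    tv_distance,
)
from walklink.samplers import empirical_pair_matrix


class TestExactPowerDistribution:
    def test_p3_a2(self, p3):
        d = exact_power_distribution(p3, 2)
        m = d.matrix
        assert m[0, 2] == pytest.approx(1 / 6)
        assert np.allclose(np.diag(m), [1 / 6, 2 / 6, 1 / 6])
        assert m.sum() == pytest.approx(1.0, abs=1e-12)

    def test_p3_a3_supported_on_edges_only(self, p3):
        m = exact_power_distribution(p3, 3).matrix
        support = set(zip(*np.nonzero(m)))
        assert support == {(0, 1), (1, 0), (1, 2), (2, 1)}
        assert np.all(m[m > 0] == pytest.approx(2 / 8))

    def test_k3_a3(self, k3):
        m = exact_power_distribution(k3, 3).matrix
        assert np.allclose(np.diag(m), 2 / 24)
        off = m[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 3 / 24)

    def test_edgeless_rejected(self):
        lone = Network(3, [(0, 1)])
        exact_power_distribution(lone, 2)  # fine
        with pytest.raises(ValueError):
            exact_power_distribution(Network.from_adjacency(np.zeros((3, 3), int)), 2)


class TestBuildA2:
    def test_p3_probabilities_and_query_count(self, p3):
        o = GGMOracle(p3)
        s = build_a2(o)
        assert np.allclose(s.node_probs, [1 / 6, 4 / 6, 1 / 6])
        assert o.degree_queries == 3 and o.total_queries == 3
        assert s.preprocessing_queries == 3

    def test_k3_uniform(self, k3):
        s = build_a2(GGMOracle(k3))
        assert np.allclose(s.node_probs, 1 / 3)

    def test_star_weights(self, star4):
        s = build_a2(GGMOracle(star4))
        assert np.allclose(s.node_probs, [9 / 12, 1 / 12, 1 / 12, 1 / 12])

    def test_node_weight_identity(self):
        # sum_v k_v^2 equals ||A^2||_{1,1} exactly, in integers
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            net = generate_er(n, min(3.0, n - 2), seed=int(rng.integers(2**31)))
            if net.edge_count == 0:
                continue
            a = net.adjacency
            assert (net.degrees**2).sum() == np.linalg.matrix_power(a, 2).sum()


class TestBuildA3:
    def test_p3_pairs_and_query_count(self, p3):
        o = GGMOracle(p3)
        s = build_a3(o)
        assert sorted(map(tuple, s.ordered_pairs.tolist())) == [
            (0, 1), (1, 0), (1, 2), (2, 1)]
        assert np.allclose(s.pair_probs, 2 / 8)
        assert o.degree_queries == 3
        assert o.neighbour_queries == 4  # 2|E|
        assert s.preprocessing_queries == 3 + 4

    def test_star_and_k3_weights(self, star4, k3):
        s = build_a3(GGMOracle(star4))
        assert np.allclose(s.pair_probs, 3 / 18)
        s = build_a3(GGMOracle(k3))
        assert len(s.pair_probs) == 6
        assert np.allclose(s.pair_probs, 4 / 24)

    def test_edge_weight_identity(self):
        # Z = sum over ordered adjacent pairs of k_u k_v equals ||A^3||_{1,1}
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            net = generate_er(n, min(3.0, n - 2), seed=int(rng.integers(2**31)))
            if net.edge_count == 0:
                continue
            k = net.degrees
            z = sum(k[u] * k[v] + k[v] * k[u] for u, v in net.edges)
            assert z == np.linalg.matrix_power(net.adjacency, 3).sum()


def _gof_ok(counts, probs, alpha=0.001):
    """Chi-square goodness of fit restricted to the support."""
    counts = np.asarray(counts, float).ravel()
    probs = np.asarray(probs, float).ravel()
    support = probs > 0
    assert counts[~support].sum() == 0, "sampler hit a zero-probability cell"
    expected = probs[support] * counts.sum()
    _, p = stats.chisquare(counts[support], expected)
    return p > alpha


@pytest.mark.parametrize("graph_name", ["p3", "star4", "c4", "k3", "er30"])
@pytest.mark.parametrize("n_power", [2, 3])
def test_sampler_marginal_matches_exact_distribution(graph_name, n_power, request):
    """10^5 draws agree with the exact A^n law in TV distance and chi-square."""
    net = request.getfixturevalue(graph_name)
    exact = exact_power_distribution(net, n_power).matrix
    rng = np.random.default_rng(777)
    oracle = GGMOracle(net)
    n_draws = 10**5
    if n_power == 2:
        s = build_a2(oracle)
        samples = [draw_a2(s, oracle, rng) for _ in range(n_draws)]
    else:
        s = build_a3(oracle)
        samples = [draw_a3(s, rng) for _ in range(n_draws)]
    counts = empirical_pair_matrix(samples, net.node_count) * n_draws
    assert tv_distance(counts / n_draws, exact) <= 0.02
    assert _gof_ok(counts, exact)


class TestDrawSemantics:
    def test_a2_per_draw_queries(self, er30, rng):
        o = GGMOracle(er30)
        s = build_a2(o)
        base = o.counter_snapshot()
        n = 500
        for _ in range(n):
            out = draw_a2(s, o, rng)
            assert out.queries_spent == 3
        assert o.neighbour_queries - base["neighbour"] == 2 * n
        assert o.pair_queries - base["pair"] == n
        assert o.degree_queries == base["degree"]

    def test_a3_draws_are_query_free(self, er30, rng):
        o = GGMOracle(er30)
        s = build_a3(o)
        base = o.total_queries
        for _ in range(500):
            assert draw_a3(s, rng).queries_spent == 0
        assert o.total_queries == base

    def test_single_edge_a2_never_useful(self, single_edge, rng):
        # A^2 of one edge is the identity: every draw has i == j
        o = GGMOracle(single_edge)
        s = build_a2(o)
        samples = [draw_a2(s, o, rng) for _ in range(2000)]
        assert all(x.i == x.j for x in samples)
        assert not any(x.useful for x in samples)

    def test_k3_a2_never_useful(self, k3, rng):
        o = GGMOracle(k3)
        s = build_a2(o)
        assert not any(draw_a2(s, o, rng).useful for _ in range(2000))

    def test_c4_a3_never_useful(self, c4, rng):
        # bipartite: opposite corners connect only by even paths
        o = GGMOracle(c4)
        s = build_a3(o)
        assert not any(draw_a3(s, rng).useful for _ in range(2000))

    def test_useful_flag_matches_good_mask(self, er30, rng):
        from walklink import good_link_matrix

        g = good_link_matrix(er30)
        o = GGMOracle(er30)
        s = build_a2(o)
        for _ in range(1000):
            out = draw_a2(s, o, rng)
            assert out.useful == bool(g[out.i, out.j])


class TestQueryCostReport:
    def test_a3_total_is_graph_size(self, er30, rng):
        o = GGMOracle(er30)
        s = build_a3(o)
        for _ in range(100):
            draw_a3(s, rng)
        rep = query_cost_report(o, preprocessing_queries=s.preprocessing_queries,
                                draws=100, n_useful=42, per_draw_queries=0)
        assert rep["total_queries"] == er30.node_count + 2 * er30.edge_count
        assert rep["sampling_queries"] == 0

    def test_a2_phase_split(self, er30, rng):
        o = GGMOracle(er30)
        s = build_a2(o)
        useful = sum(draw_a2(s, o, rng).useful for _ in range(200))
        rep = query_cost_report(o, preprocessing_queries=s.preprocessing_queries,
                                draws=200, n_useful=useful, per_draw_queries=3)
        assert rep["preprocessing_queries"] == er30.node_count
        assert rep["sampling_queries"] == 3 * 200 == rep["expected_sampling_queries"]
        assert rep["p_hat_G"] == useful / 200

    def test_zero_draws(self, p3):
        o = GGMOracle(p3)
        s = build_a2(o)
        rep = query_cost_report(o, preprocessing_queries=s.preprocessing_queries,
                                draws=0, n_useful=0, per_draw_queries=3)
        assert rep["sampling_queries"] == 0
        assert np.isnan(rep["p_hat_G"])
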