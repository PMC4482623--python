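import math

import networkx as nx
import numpy as np
import pytest

from lsed.centrality import (
    Method,
    MethodSpec,
    compute_centrality,
    edge_clustering_coefficient,
    external_scores,
    nc_centrality,
)

TOL = 1e-9


def _spec(method, **kw):
    return MethodSpec(method=Method(method), **kw)


def random_graphs(count, max_n, seed0=0, connected=False):
    """Seeded Erdos-Renyi graphs with string node labels."""
    graphs = []
    rng = np.random.default_rng(seed0)
    while len(graphs) < count:
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.1, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if connected and not nx.is_connected(g):
            continue
        graphs.append(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
    return graphs


# ---------------------------------------------------------------------------
# independent oracles


def brute_betweenness(net):
    """Shortest-path betweenness from scratch via adjacency matrix powers.

    A walk of minimal length between two nodes cannot revisit a node, so the
    (s, t) entry of A^d counts shortest paths once d is the first power with
    a nonzero entry.  Path counts through v follow by splitting at v.
    """
    nodes = list(net.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(net, nodelist=nodes).astype(object)
    dist = -np.ones((n, n), dtype=int)
    sigma = np.zeros((n, n), dtype=object)
    np.fill_diagonal(dist, 0)
    np.fill_diagonal(sigma, 1)
    power = np.eye(n, dtype=object)
    for k in range(1, n):
        power = power @ A
        fresh = (dist == -1) & (power > 0)
        dist[fresh] = k
        sigma[fresh] = power[fresh]
    bc = {v: 0.0 for v in nodes}
    for s in range(n):
        for t in range(s + 1, n):
            if dist[s, t] <= 0:
                continue
            for v in range(n):
                if v in (s, t) or dist[s, v] < 0 or dist[v, t] < 0:
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    bc[nodes[v]] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def brute_nc(net):
    """NC via the adjacency-square common-neighbor count."""
    nodes = list(net.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = nx.to_numpy_array(net, nodelist=nodes)
    A2 = A @ A
    scores = {v: 0.0 for v in nodes}
    for u, v in net.edges:
        z = A2[index[u], index[v]]
        denom = min(net.degree(u) - 1, net.degree(v) - 1)
        ecc = z / denom if denom > 0 else 0.0
        scores[u] += ecc
        scores[v] += ecc
    return scores


def walk_series_sc(net, terms=40):
    """Subgraph centrality as the truncated closed-walk series sum_k (A^k)_vv / k!."""
    nodes = list(net.nodes)
    A = nx.to_numpy_array(net, nodelist=nodes)
    total = np.zeros(len(nodes))
    power = np.eye(len(nodes))
    for k in range(terms + 1):
        total += np.diag(power) / math.factorial(k)
        power = power @ A
    return {v: total[i] for i, v in enumerate(nodes)}


def resistance_ic(net):
    """Information centrality via effective resistances from the Laplacian
    pseudoinverse: score(i) = m / sum_j R_ij per component."""
    scores = {v: 0.0 for v in net.nodes}
    for component in nx.connected_components(net):
        m = len(component)
        if m < 2:
            continue
        nodes = sorted(component)
        sub = net.subgraph(nodes)
        L = nx.laplacian_matrix(sub, nodelist=nodes).toarray().astype(float)
        Lp = np.linalg.pinv(L)
        d = np.diag(Lp)
        R = d[:, None] + d[None, :] - 2 * Lp
        for i, v in enumerate(nodes):
            scores[v] = m / R[i].sum()
    return scores


# ---------------------------------------------------------------------------


class TestClosedFormExamples:
    def test_dc_triangle(self, triangle):
        assert compute_centrality(triangle, _spec("DC")) == {"a": 2.0, "b": 2.0, "c": 2.0}

    def test_bc_path(self, path3):
        assert compute_centrality(path3, _spec("BC")) == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_sc_isolated_node(self):
        g = nx.Graph()
        g.add_node("a")
        assert compute_centrality(g, _spec("SC"))["a"] == pytest.approx(1.0, abs=TOL)

    def test_sc_single_edge_closed_form(self):
        # adjacency eigenvalues +-1: diagonal of e^A is cosh(1)
        g = nx.Graph([("a", "b")])
        expected = (math.e + 1 / math.e) / 2
        for score in compute_centrality(g, _spec("SC")).values():
            assert score == pytest.approx(expected, abs=TOL)

    def test_ic_single_edge(self):
        g = nx.Graph([("a", "b")])
        assert compute_centrality(g, _spec("IC")) == pytest.approx({"a": 2.0, "b": 2.0}, abs=TOL)

    def test_ec_triangle_symmetry(self, triangle):
        scores = compute_centrality(triangle, _spec("EC"))
        for v in "abc":
            assert scores[v] == pytest.approx(1 / math.sqrt(3), abs=TOL)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            compute_centrality(nx.Graph(), _spec("DC"))


class TestClosenessModes:
    def test_strict_zeros_on_disconnected(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e")])
        assert set(compute_centrality(g, _spec("CC")).values()) == {0.0}

    def test_strict_on_connected_path(self, path3):
        scores = compute_centrality(path3, _spec("CC"))
        assert scores["b"] == pytest.approx(1.0)
        assert scores["a"] == scores["c"] == pytest.approx(2 / 3)

    def test_component_mode_scores_within_components(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("d", "e")])
        g.add_node("z")
        scores = compute_centrality(g, _spec("CC", cc_mode="component"))
        assert scores["a"] == scores["b"] == pytest.approx(1.0)
        assert scores["d"] == pytest.approx(1.0)
        assert scores["c"] == scores["e"] == pytest.approx(2 / 3)
        assert scores["z"] == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            MethodSpec(method=Method.CC, cc_mode="bogus")


class TestEdgeClustering:
    def test_triangle_edge(self, triangle):
        assert edge_clustering_coefficient(triangle, "a", "b") == 1.0

    def test_square_edge_has_no_triangles(self):
        square = nx.cycle_graph(4)
        assert edge_clustering_coefficient(square, 0, 1) == 0.0

    def test_pendant_edge_guard(self, path3):
        assert edge_clustering_coefficient(path3, "a", "b") == 0.0

    def test_missing_edge_rejected(self, path3):
        with pytest.raises(ValueError):
            edge_clustering_coefficient(path3, "a", "c")

    def test_nc_triangle(self, triangle):
        assert nc_centrality(triangle) == {"a": 2.0, "b": 2.0, "c": 2.0}

    def test_nc_triangle_free(self, path3):
        assert set(nc_centrality(path3).values()) == {0.0}


class TestOracleAgreement:
    @pytest.mark.parametrize("graph", random_graphs(40, 8), ids=range(40))
    def test_bc_and_nc_match_brute_force(self, graph):
        bc = compute_centrality(graph, _spec("BC"))
        brute = brute_betweenness(graph)
        for v in graph.nodes:
            assert bc[v] == pytest.approx(brute[v], abs=TOL)
        nc = compute_centrality(graph, _spec("NC"))
        brute_n = brute_nc(graph)
        for v in graph.nodes:
            assert nc[v] == pytest.approx(brute_n[v], abs=TOL)
        dc = compute_centrality(graph, _spec("DC"))
        for v in graph.nodes:
            assert dc[v] == graph.degree(v)

    @pytest.mark.parametrize("graph", random_graphs(20, 8, seed0=1), ids=range(20))
    def test_sc_matches_walk_series(self, graph):
        sc = compute_centrality(graph, _spec("SC"))
        series = walk_series_sc(graph)
        for v in graph.nodes:
            assert sc[v] == pytest.approx(series[v], abs=TOL)

    @pytest.mark.parametrize("graph", random_graphs(20, 10, seed0=2, connected=True), ids=range(20))
    def test_ic_matches_resistance_oracle(self, graph):
        ic = compute_centrality(graph, _spec("IC"))
        oracle = resistance_ic(graph)
        for v in graph.nodes:
            assert ic[v] == pytest.approx(oracle[v], abs=TOL)

    @pytest.mark.parametrize("graph", random_graphs(10, 10, seed0=3, connected=True), ids=range(10))
    def test_ic_consistent_with_current_flow_closeness(self, graph):
        """Cross-check: same values as networkx current-flow closeness up to
        the factor m between the two conventional normalizations (networkx
        returns 1 / sum of effective resistances; here m / that sum)."""
        m = graph.number_of_nodes()
        ic = compute_centrality(graph, _spec("IC"))
        nx_ic = nx.information_centrality(graph)
        for v in graph.nodes:
            assert ic[v] == pytest.approx(nx_ic[v] * m, abs=1e-8)

    @pytest.mark.parametrize("graph", random_graphs(20, 12, seed0=4), ids=range(20))
    def test_ec_satisfies_eigen_equation(self, graph):
        scores = compute_centrality(graph, _spec("EC"))
        for component in nx.connected_components(graph):
            if len(component) < 2:
                assert all(scores[v] == 0.0 for v in component)
                continue
            nodes = sorted(component)
            A = nx.to_numpy_array(graph.subgraph(nodes), nodelist=nodes)
            x = np.array([scores[v] for v in nodes])
            lam = float(np.max(np.linalg.eigvalsh(A)))
            assert np.allclose(A @ x, lam * x, atol=1e-8)
        norm = math.sqrt(sum(s * s for s in scores.values()))
        if norm:
            assert norm == pytest.approx(1.0, abs=1e-8)

    def test_sc_cross_check_networkx(self):
        graph = random_graphs(1, 8, seed0=5, connected=True)[0]
        sc = compute_centrality(graph, _spec("SC"))
        reference = nx.subgraph_centrality(graph)
        for v in graph.nodes:
            assert sc[v] == pytest.approx(reference[v], abs=1e-8)


@pytest.mark.parametrize("method", ["DC", "BC", "CC", "SC", "EC", "IC", "NC"])
def test_label_invariance(method):
    """Relabeling nodes permutes every method's scores identically."""
    rng = np.random.default_rng(11)
    for trial in range(5):
        n = int(rng.integers(4, 12))
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        mapping = {v: f"m{rng.integers(1e6)}_{v}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        spec = _spec(method)
        scores_g = compute_centrality(g, spec)
        scores_h = compute_centrality(h, spec)
        for v in g.nodes:
            assert scores_h[mapping[v]] == pytest.approx(scores_g[v], abs=1e-8)


def test_all_scores_finite_nonnegative_full_domain(small_truth):
    """Every method returns a finite score >= 0 for exactly the node set."""
    sub = small_truth.graph.subgraph(sorted(small_truth.graph.nodes)[:60])
    for method in ["DC", "BC", "CC", "SC", "EC", "IC", "NC"]:
        scores = compute_centrality(nx.Graph(sub), _spec(method))
        assert set(scores) == set(sub.nodes)
        assert all(np.isfinite(s) and s >= 0 for s in scores.values())


class TestExternalScores:
    def test_full_table(self, path3, tmp_path):
        table = tmp_path / "scores.tsv"
        table.write_text("a\t1.5\nb\t2\nc\t0\n")
        assert external_scores(path3, table) == {"a": 1.5, "b": 2.0, "c": 0.0}

    def test_empty_table_all_zero(self, path3, tmp_path):
        (tmp_path / "scores.tsv").write_text("")
        assert set(external_scores(path3, tmp_path / "scores.tsv").values()) == {0.0}

    def test_extraneous_ids_ignored(self, path3, tmp_path):
        table = tmp_path / "scores.tsv"
        table.write_text("a\t1\nzz\t9\n")
        assert external_scores(path3, table) == {"a": 1.0, "b": 0.0, "c": 0.0}

    def test_negative_score_rejected(self, path3, tmp_path):
        table = tmp_path / "scores.tsv"
        table.write_text("a\t-1\n")
        with pytest.raises(ValueError):
            external_scores(path3, table)
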