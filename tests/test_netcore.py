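"""Graph construction, the six centralities against brute-force oracles, and
the two-stage screening cascade."""

import math

import networkx as nx
import numpy as np
import pytest

from netpharm.netcore import (
    CascadeConfig,
    GraphInputError,
    build_ct_network,
    centralities,
    intersect_networks,
    neighborhood_network,
    read_ppi_tsv,
    run_cascade,
    screen_stage,
)
from netpharm.synthetic import gen_ppi


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation paths)


def bc_oracle(g):
    """Betweenness by explicit enumeration of every geodesic of every
    unordered pair; interior vertices share each pair's unit weight."""
    nodes = list(g.nodes())
    bc = dict.fromkeys(nodes, 0.0)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            try:
                paths = list(nx.all_shortest_paths(g, s, t))
            except nx.NetworkXNoPath:
                continue
            w = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += w
    return bc


def cct_oracle(g):
    n = g.number_of_nodes()
    out = {}
    for v in g.nodes():
        dist = nx.single_source_shortest_path_length(g, v)
        r = len(dist) - 1
        total = sum(dist.values())
        out[v] = (r / (n - 1)) * (r / total) if total > 0 and n > 1 else 0.0
    return out


def ec_oracle(g):
    """Dense symmetric eigen-solve on the largest component."""
    scores = dict.fromkeys(g.nodes(), 0.0)
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    nodes = sorted(comp)
    if len(nodes) == 1:
        scores[nodes[0]] = 1.0
        return scores
    a = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, np.argmax(w)])
    vec /= np.linalg.norm(vec)
    for node, val in zip(nodes, vec):
        scores[node] = float(val)
    return scores


def lac_oracle(g):
    out = {}
    for v in g.nodes():
        nbrs = set(g.neighbors(v))
        if not nbrs:
            out[v] = 0.0
            continue
        sub = g.subgraph(nbrs)
        out[v] = sum(d for _, d in sub.degree()) / len(nbrs)
    return out


def nc_oracle(g):
    out = {}
    for v in g.nodes():
        total = 0.0
        for w in g.neighbors(v):
            denom = min(g.degree(v) - 1, g.degree(w) - 1)
            if denom > 0:
                z = len(set(g.neighbors(v)) & set(g.neighbors(w)))
                total += z / denom
        out[v] = total
    return out


ORACLES = {"BC": bc_oracle, "CCT": cct_oracle, "EC": ec_oracle,
           "LAC": lac_oracle, "NC": nc_oracle}


# ---------------------------------------------------------------------------


class TestClosedForms:
    def test_star_center(self):
        g = nx.star_graph(3)  # center 0
        c = centralities(g)
        assert c.loc[0, "DC"] == 3
        assert c.loc[0, "BC"] == 3        # all 3 leaf pairs route through it
        assert c.loc[0, "CCT"] == 1.0
        assert c.loc[0, "LAC"] == 0.0     # leaves not interconnected
        assert c.loc[0, "NC"] == 0.0      # no triangles

    def test_triangle_node(self):
        c = centralities(nx.complete_graph(3))
        assert c.loc[0, "DC"] == 2
        assert c.loc[0, "BC"] == 0
        assert c.loc[0, "CCT"] == 1.0
        assert c.loc[0, "EC"] == pytest.approx(1 / math.sqrt(3), abs=1e-9)
        assert c.loc[0, "LAC"] == 1.0
        assert c.loc[0, "NC"] == 2.0

    def test_path_betweenness(self):
        c = centralities(nx.path_graph(3), ("BC",))
        assert c.loc[1, "BC"] == 1
        assert c.loc[0, "BC"] == 0
        assert c.loc[2, "BC"] == 0

    def test_empty_graph(self):
        assert centralities(nx.Graph()).empty


class TestOracleEquivalence:
    def test_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(1234)
        worst = 0.0
        for trial in range(50):
            n = int(rng.integers(5, 41))
            p = float(rng.uniform(0.08, 0.35))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            c = centralities(g)
            for metric, oracle in ORACLES.items():
                ref = oracle(g)
                dev = max(abs(c.loc[v, metric] - ref[v]) for v in g.nodes()) \
                    if g.number_of_nodes() else 0.0
                worst = max(worst, dev)
        assert worst <= 1e-8

    def test_tree_betweenness_counts_pairs_through_vertex(self):
        g = nx.random_labeled_tree(25, seed=9)
        c = centralities(g, ("BC",))
        for v in g.nodes():
            count = 0
            nodes = list(g.nodes())
            for i, s in enumerate(nodes):
                for t in nodes[i + 1:]:
                    if v in (s, t):
                        continue
                    if v in nx.shortest_path(g, s, t):
                        count += 1
            assert c.loc[v, "BC"] == pytest.approx(count, abs=1e-9)

    def test_isomorphism_invariance(self):
        g = nx.gnp_random_graph(20, 0.2, seed=4)
        mapping = {v: f"node_{v}" for v in g.nodes()}
        h = nx.relabel_nodes(g, mapping)
        cg, ch = centralities(g), centralities(h)
        for v in g.nodes():
            np.testing.assert_allclose(
                cg.loc[v].to_numpy(), ch.loc[mapping[v]].to_numpy(), atol=1e-9
            )


class TestConstruction:
    def test_ct_network_hand_enumeration(self):
        net = build_ct_network({"c1": {"A", "B"}, "c2": {"B"}}, {"B", "C"})
        assert set(net.compounds) == {"c1", "c2"}
        assert set(net.targets) == {"B"}
        assert sorted(net.edges) == [("c1", "B"), ("c2", "B")]
        assert net.compound_degrees()[0][1] == 1  # tie at degree 1

    def test_ct_network_disjoint_disease(self):
        net = build_ct_network({"c1": {"A"}}, {"Z"})
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_ct_network_star(self):
        net = build_ct_network({"c1": {"A", "B", "C"}}, {"A", "B", "C"})
        assert net.n_nodes == 4 and net.n_edges == 3

    def test_neighborhood_one_hop(self):
        ppi = nx.path_graph(["a", "b", "c"])
        sub = neighborhood_network({"a"}, ppi)
        assert set(sub.nodes()) == {"a", "b"}
        assert list(sub.edges()) == [("a", "b")]

    def test_neighborhood_closure(self):
        ppi = nx.gnp_random_graph(15, 0.3, seed=2)
        sub = neighborhood_network(set(ppi.nodes()), ppi)
        assert nx.utils.graphs_equal(sub, ppi)

    def test_neighborhood_absent_seed(self):
        assert neighborhood_network({"x"}, nx.path_graph(3)).number_of_nodes() == 0

    def test_intersection_idempotent_and_commutative(self):
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        assert nx.utils.graphs_equal(intersect_networks(g, g), g)
        h = nx.gnp_random_graph(12, 0.3, seed=4)
        a, b = intersect_networks(g, h), intersect_networks(h, g)
        assert nx.utils.graphs_equal(a, b)

    def test_intersection_triangle_vs_path(self):
        tri = nx.complete_graph(["a", "b", "c"])
        path = nx.path_graph(["a", "b", "c"])
        out = intersect_networks(tri, path)
        assert set(out.nodes()) == {"a", "b", "c"}
        assert {tuple(sorted(e)) for e in out.edges()} == {("a", "b"), ("b", "c")}

    def test_intersection_disjoint(self):
        out = intersect_networks(nx.path_graph([1, 2]), nx.path_graph([3, 4]))
        assert out.number_of_nodes() == 0

    def test_read_ppi_drops_self_loops_and_dupes(self, tmp_path):
        p = tmp_path / "ppi.tsv"
        p.write_text("a\tb\nb\ta\nc\tc\na\tpp\tb\n")
        g = read_ppi_tsv(p)
        assert set(g.nodes()) == {"a", "b"}
        assert g.number_of_edges() == 1


class TestScreening:
    def test_exact_threshold_removed(self):
        g = nx.path_graph(3)
        scores = centralities(g, ("DC",))
        out = screen_stage(g, scores, ("DC",), {"DC": 2})
        assert 1 not in out.nodes()  # middle node has DC exactly 2

    def test_vacuous_filter(self):
        g = nx.gnp_random_graph(10, 0.3, seed=5)
        scores = centralities(g)
        out = screen_stage(g, scores, tuple(scores.columns),
                           {m: -math.inf for m in scores.columns})
        assert nx.utils.graphs_equal(out, g)

    def test_degree_boundary_61(self):
        g = nx.Graph()
        hub_a, hub_b, hub_c = "a", "b", "c"
        for i in range(5):
            g.add_edge(hub_a, f"x{i}")
        for i in range(61):
            g.add_edge(hub_b, f"y{i}")
        for i in range(62):
            g.add_edge(hub_c, f"z{i}")
        scores = centralities(g, ("DC",))
        out = screen_stage(g, scores, ("DC",), {"DC": 61})
        assert set(out.nodes()) == {hub_c}

    def test_missing_metric_is_config_error(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError, match="BC"):
            screen_stage(g, centralities(g, ("DC",)), ("BC",), {"BC": 0})

    def test_complete_graph_ties_eliminate_everything(self):
        res = run_cascade(nx.complete_graph(10), CascadeConfig(dc_abs=0))
        assert res.final_nodes == []

    def test_cascade_nesting_property(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.1, 0.4)),
                                    seed=int(rng.integers(2**31)))
            if g.number_of_nodes() == 0:
                continue
            res = run_cascade(g)
            stage1_nodes = res.stages[1]["n_nodes"]
            assert stage1_nodes <= g.number_of_nodes()
            assert len(res.final_nodes) <= stage1_nodes

    def test_cascade_records_medians_of_inputs(self):
        g, _ = gen_ppi(n_nodes=150, core_size=10, seed=5)
        res = run_cascade(g)
        dc = centralities(g, ("DC",))["DC"].to_numpy()
        assert res.stages[1]["dc_median"] == pytest.approx(float(np.median(dc)))
        assert res.stages[1]["threshold"] == pytest.approx(2.0 * float(np.median(dc)))

    def test_cascade_recovers_planted_core_single_seed(self):
        g, entry = gen_ppi(seed=0)
        core = set(entry["core_nodes"])
        got = set(run_cascade(g).final_nodes)
        assert len(got & core) / len(core) >= 0.8
        assert len(got & core) / len(got) >= 0.8

    def test_raising_threshold_shrinks_survivors(self):
        g, _ = gen_ppi(n_nodes=200, core_size=10, seed=8)
        scores = centralities(g, ("DC",))
        low = screen_stage(g, scores, ("DC",), {"DC": 5})
        high = screen_stage(g, scores, ("DC",), {"DC": 10})
        assert set(high.nodes()) <= set(low.nodes())

    def test_empty_graph_rejected(self):
        with pytest.raises(GraphInputError):
            run_cascade(nx.Graph())
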