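from collections import deque

import networkx as nx
import numpy as np
import pytest

from occnet import (
    FragmentAnnotation,
    ValidationError,
    build_cooccurrence_network,
    build_rule_network,
    degree_domain_profile,
    er_baseline,
    er_random_graph,
    hub_neighborhood,
    hub_roles,
    modularity_partition,
    modularity_q,
    rule_cooccurrence_intersection,
    topology,
)
from occnet.cooccurrence import PairTestResult
from occnet.data import ContingencyTable2x2
from occnet.rules import AssociationRule
from occnet.topology import _clustering_mean, _cpl, _degree_stats, _undirected_adjacency


def pair(f1, f2, significant=True, sign="positive", p_adj=0.01):
    return PairTestResult(f1, f2, ContingencyTable2x2(1, 0, 0, 1), 0.5, p_adj, significant, sign)


def rule(o, t):
    return AssociationRule(o, t, 1, 1)


# --- pure-Python brute-force oracles ---------------------------------------


def bfs_oracle_cpl(g: nx.Graph) -> float:
    dists = []
    for src in g.nodes:
        seen = {src: 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in g.neighbors(u):
                if v not in seen:
                    seen[v] = seen[u] + 1
                    queue.append(v)
        dists.extend(d for n, d in seen.items() if n != src)
    return sum(dists) / len(dists)


def triangle_oracle_clustering(g: nx.Graph) -> float:
    vals = []
    for n in g.nodes:
        nbrs = list(g.neighbors(n))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for i in range(k) for j in range(i + 1, k) if g.has_edge(nbrs[i], nbrs[j]))
        vals.append(2 * links / (k * (k - 1)))
    return sum(vals) / len(vals)


def degree_oracle(g: nx.Graph) -> tuple[float, float]:
    deg = [d for _, d in g.degree]
    n = len(deg)
    cent = sum(max(deg) - d for d in deg) / ((n - 1) * (n - 2))
    mean = sum(deg) / n
    sd = (sum((d - mean) ** 2 for d in deg) / n) ** 0.5
    return cent, sd / mean


# --- construction -----------------------------------------------------------


class TestBuild:
    def test_cooccurrence_nodes_and_edges(self):
        results = [pair("A", "B"), pair("B", "C", sign="negative"), pair("C", "D", significant=False)]
        g = build_cooccurrence_network(results)
        assert set(g.nodes) == {"A", "B", "C"}
        assert g.number_of_edges() == 2
        assert g.edges["B", "C"]["sign"] == "negative"

    def test_zero_significant_pairs_empty_network(self):
        g = build_cooccurrence_network([pair("A", "B", significant=False)])
        assert g.number_of_nodes() == 0

    def test_triangle(self):
        g = build_cooccurrence_network([pair("A", "B"), pair("B", "C"), pair("A", "C")])
        assert nx.is_isomorphic(g, nx.complete_graph(3))

    def test_rule_network_star_and_reciprocal(self):
        g = build_rule_network([rule("A", "B"), rule("C", "B")])
        assert g.in_degree["B"] == 2 and g.out_degree["B"] == 0
        g2 = build_rule_network([rule("A", "B"), rule("B", "A")])
        assert g2.number_of_edges() == 2
        assert build_rule_network([]).number_of_nodes() == 0


# --- topology metrics -------------------------------------------------------


class TestTopologyMetrics:
    def test_closed_forms_on_k5(self):
        t = topology(nx.complete_graph(5))
        assert t.density == 1.0
        assert t.characteristic_path_length == 1.0
        assert t.clustering_coefficient == 1.0
        assert t.centralization == 0.0
        assert t.heterogeneity == 0.0

    def test_path_graph_p3(self):
        t = topology(nx.path_graph(3))
        assert t.characteristic_path_length == pytest.approx(4 / 3)
        assert t.clustering_coefficient == 0.0

    def test_star_centralization_is_one(self):
        t = topology(nx.star_graph(9))
        assert t.centralization == pytest.approx(1.0)

    def test_density_and_avg_neighbors_closed_forms(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = nx.gnm_random_graph(20, int(rng.integers(5, 60)), seed=int(rng.integers(2**31)))
            t = topology(g)
            n, e = g.number_of_nodes(), g.number_of_edges()
            assert t.density == pytest.approx(2 * e / (n * (n - 1)))
            assert t.avg_neighbors == pytest.approx(2 * e / n)

    def test_matches_brute_force_oracles(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = nx.gnm_random_graph(30, 60, seed=int(rng.integers(2**31)))
            adj, _ = _undirected_adjacency(g)
            assert _cpl(adj) == pytest.approx(bfs_oracle_cpl(g))
            assert _clustering_mean(adj) == pytest.approx(triangle_oracle_clustering(g))
            cent, het = _degree_stats(adj)
            o_cent, o_het = degree_oracle(g)
            assert cent == pytest.approx(o_cent) and het == pytest.approx(o_het)

    def test_directed_collapse_merges_reciprocal_edges(self):
        g = build_rule_network([rule("A", "B"), rule("B", "A"), rule("B", "C")])
        t = topology(g)
        assert t.n_edges == 2  # A<->B merges

    def test_coverage(self):
        t = topology(nx.complete_graph(4), all_fragments_count=8)
        assert t.coverage == pytest.approx(0.5)

    def test_disconnected_pairs_excluded_from_cpl(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        t = topology(g)
        assert t.characteristic_path_length == 1.0

    def test_no_connected_pair_is_error(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        with pytest.raises(ValidationError):
            topology(g)

    def test_small_network_centralization_error(self):
        with pytest.raises(ValidationError):
            topology(nx.path_graph(2))


# --- Erdos-Renyi baseline ---------------------------------------------------


class TestErBaseline:
    def test_forced_complete_graph(self):
        g = er_random_graph(4, 6, seed=0)
        assert nx.is_isomorphic(g, nx.complete_graph(4))

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValidationError):
            er_random_graph(4, 7, seed=0)

    def test_deterministic_under_seed(self):
        g1 = er_random_graph(30, 50, seed=9)
        g2 = er_random_graph(30, 50, seed=9)
        assert set(g1.edges) == set(g2.edges)

    def test_mean_clustering_tracks_density(self):
        # in G(n, m) the expected local clustering equals the edge density
        n, m = 60, 400
        base = er_baseline(n, m, n_reps=60, seed=3)
        density = 2 * m / (n * (n - 1))
        assert abs(base.mean_clustering - density) < 3 * base.clustering_sem


# --- modularity -------------------------------------------------------------


class TestModularity:
    def test_two_disjoint_triangles(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")])
        part = modularity_partition(g)
        assert part.n_modules == 2
        assert part.q == pytest.approx(0.5)
        assert part.membership["A"] == part.membership["B"] == part.membership["C"]

    def test_single_clique_q_zero(self):
        part = modularity_partition(nx.complete_graph(5))
        assert part.n_modules == 1
        assert part.q == pytest.approx(0.0)

    def test_q_equals_direct_formula_and_networkx(self):
        g = nx.gnm_random_graph(40, 80, seed=4)
        part = modularity_partition(g)
        comms: dict[int, set] = {}
        for node, c in part.membership.items():
            comms.setdefault(c, set()).add(int(node))
        ref = nx.community.modularity(g, comms.values())
        assert part.q == pytest.approx(ref)
        # direct evaluation also for a non-optimal partition
        arbitrary = {n: n % 3 for n in g.nodes}
        assert modularity_q(g, arbitrary) == pytest.approx(
            nx.community.modularity(g, [{n for n in g if n % 3 == k} for k in range(3)])
        )

    def test_positive_edges_only(self):
        results = [pair("A", "B"), pair("B", "C", sign="negative"), pair("A", "C")]
        part = modularity_partition(build_cooccurrence_network(results))
        assert set(part.membership) == {"A", "B", "C"}  # C joins via positive A-C edge

    def test_requires_positive_edge(self):
        results = [pair("A", "B", sign="negative")]
        with pytest.raises(ValidationError):
            modularity_partition(build_cooccurrence_network(results))


# --- degree profile and hubs ------------------------------------------------


def ann(**domains):
    return {f: FragmentAnnotation(f, d) for f, d in domains.items()}


class TestDegreeProfileAndHubs:
    def test_all_bacterial_triangle(self):
        g = build_cooccurrence_network([pair("A", "B"), pair("B", "C"), pair("A", "C")])
        prof = degree_domain_profile(g, ann(A="bacterial", B="bacterial", C="bacterial"))
        assert prof.to_dict("records") == [
            {"degree": 2, "n_nodes": 3, "fraction_bacterial": 1.0}
        ]

    def test_archaeal_hub_star(self):
        g = build_cooccurrence_network([pair("H", leaf) for leaf in "ABCD"])
        prof = degree_domain_profile(
            g, ann(H="archaeal", A="bacterial", B="bacterial", C="bacterial", D="bacterial")
        )
        rows = {r["degree"]: r for r in prof.to_dict("records")}
        assert rows[4] == {"degree": 4, "n_nodes": 1, "fraction_bacterial": 0.0}
        assert rows[1] == {"degree": 1, "n_nodes": 4, "fraction_bacterial": 1.0}

    def test_hub_roles_star(self):
        g = build_rule_network([rule("A", "B"), rule("C", "B"), rule("D", "B")])
        rep = hub_roles(g)
        assert rep.roles["B"] == "target_only" and rep.in_degree["B"] == 3
        assert {rep.roles[n] for n in "ACD"} == {"origin_only"}
        assert rep.top_targets == ["B"]

    def test_mixed_node_excluded_from_top_lists(self):
        g = build_rule_network([rule("A", "B"), rule("B", "C")])
        rep = hub_roles(g)
        assert rep.roles["B"] == "mixed"
        assert "B" not in rep.top_targets and "B" not in rep.top_origins

    def test_top_k_truncation_deterministic(self):
        rules = [rule(f"o{i:02d}", f"t{i:02d}") for i in range(30)]
        rep = hub_roles(build_rule_network(rules), k=25)
        assert len(rep.top_targets) == 25
        # equal in-degree ties break lexicographically
        assert rep.top_targets == sorted(rep.top_targets)

    def test_hub_neighborhood_overlay(self):
        rnet = build_rule_network([rule("A", "H"), rule("B", "H"), rule("C", "H")])
        cnet_empty = build_cooccurrence_network([pair("A", "B", significant=False)])
        n0 = hub_neighborhood(rnet, cnet_empty, "H")
        assert len(n0.rule_edges) == 3 and n0.overlay_edges == []
        cnet = build_cooccurrence_network([pair("A", "B", sign="positive")])
        n1 = hub_neighborhood(rnet, cnet, "H")
        assert n1.overlay_edges == [frozenset(("A", "B"))]
        with pytest.raises(KeyError):
            hub_neighborhood(rnet, cnet, "nope")

    def test_neighborhood_multigraph_export(self):
        rnet = build_rule_network([rule("A", "H"), rule("B", "H")])
        cnet = build_cooccurrence_network([pair("A", "B")])
        mg = hub_neighborhood(rnet, cnet, "H").as_multigraph()
        kinds = sorted(d["kind"] for _, _, d in mg.edges(data=True))
        assert kinds == ["cooccurrence", "rule", "rule"]


class TestIntersection:
    def test_disjoint_edge_sets(self):
        rnet = build_rule_network([rule("A", "B")])
        cnet = build_cooccurrence_network([pair("C", "D")])
        assert rule_cooccurrence_intersection(rnet, cnet)[0] == 0

    def test_identical_pair_sets(self):
        rnet = build_rule_network([rule("A", "B"), rule("C", "D")])
        cnet = build_cooccurrence_network([pair("A", "B"), pair("C", "D")])
        count, frac, _ = rule_cooccurrence_intersection(rnet, cnet)
        assert count == 2 and frac == 1.0

    def test_partial_overlap_fraction(self):
        rules = [rule(f"o{i}", f"t{i}") for i in range(5)]
        rnet = build_rule_network(rules)
        cnet = build_cooccurrence_network([pair("o0", "t0"), pair("o1", "t1")])
        count, frac, hits = rule_cooccurrence_intersection(rnet, cnet)
        assert count == 2 and frac == pytest.approx(0.4)
        assert hits == [("o0", "t0"), ("o1", "t1")]
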