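"""Correlation networks, Louvain communities, similarity, betweenness
summarization — with brute-force oracles for betweenness (exhaustive
shortest-path enumeration) and Louvain (exhaustive modularity maximization
on a 6-node graph)."""

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from protokg.graph_store import PropertyGraph
from protokg.networks import (betweenness_centrality, betweenness_topk,
                              build_knowledge_subgraph, correlation_network,
                              louvain_communities, project_similarity)
from protokg.prep import ExperimentMatrix


def make_matrix(values, features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{j}" for j in range(values.shape[1])]
    samples = [f"s{i}" for i in range(values.shape[0])]
    return ExperimentMatrix(
        values=pd.DataFrame(values, index=samples, columns=features),
        sample_meta=pd.DataFrame({"group": ["g"] * values.shape[0]}, index=samples),
    )


class TestCorrelationNetwork:
    def test_exact_linear_pair_kept_at_any_threshold(self):
        x = np.arange(1.0, 11.0)
        m = make_matrix(np.column_stack([x, 2 * x]))
        net = correlation_network(m, min_coefficient=0.99)
        assert len(net.edges) == 1
        assert net.edges["coefficient"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_yields_no_edges_at_defaults(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(50, 10)))
        net = correlation_network(m)
        assert len(net.edges) == 0

    def test_monotone_nonlinear_pair_spearman_vs_pearson(self):
        x = np.linspace(0, 5, 20)
        m = make_matrix(np.column_stack([x, np.exp(x)]))
        rho = correlation_network(m, method="spearman").edges
        r = correlation_network(m, method="pearson").edges
        assert rho["coefficient"].iloc[0] == pytest.approx(1.0)
        assert r["coefficient"].iloc[0] < 1.0

    def test_signed_rule_drops_strong_anticorrelation_by_default(self):
        x = np.arange(1.0, 21.0)
        m = make_matrix(np.column_stack([x, -x + np.linspace(0, 0.1, 20)]))
        assert len(correlation_network(m).edges) == 0
        assert len(correlation_network(m, absolute=True).edges) == 1

    def test_constant_feature_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(10, 3))
        vals[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            net = correlation_network(make_matrix(vals))
        assert net.excluded == ["f2"]

    def test_bipartite_blocks_test_only_cross_pairs(self):
        x = np.arange(1.0, 16.0)
        vals = np.column_stack([x, x + 0.001, x * 2])  # all mutually correlated
        m = make_matrix(vals, features=["clinA", "protB", "protC"])
        net = correlation_network(m, blocks=(["clinA"], ["protB", "protC"]))
        pairs = set(map(tuple, net.edges[["source", "target"]].to_numpy()))
        assert pairs == {("clinA", "protB"), ("clinA", "protC")}

    def test_edge_set_invariant_to_orderings(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(25, 6))
        vals[:, 1] = vals[:, 0] + rng.normal(0, 0.3, 25)
        m1 = make_matrix(vals)
        perm_feat = ["f3", "f0", "f5", "f1", "f4", "f2"]
        m2 = ExperimentMatrix(values=m1.values[perm_feat].sample(frac=1, random_state=1),
                              sample_meta=m1.sample_meta)
        e1 = {tuple(sorted(p)) for p in m_edges(m1)}
        e2 = {tuple(sorted(p)) for p in m_edges(m2)}
        assert e1 == e2


def m_edges(matrix):
    net = correlation_network(matrix)
    return map(tuple, net.edges[["source", "target"]].to_numpy())


def manual_modularity(graph: nx.Graph, partition):
    m = graph.number_of_edges()
    q = 0.0
    for community in partition:
        community = set(community)
        lc = sum(1 for u, v in graph.edges if u in community and v in community)
        dc = sum(graph.degree(n) for n in community)
        q += lc / m - (dc / (2 * m)) ** 2
    return q


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [subset + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


class TestLouvain:
    def two_triangles(self):
        g = nx.Graph()
        g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        return g

    def test_two_triangles_match_exhaustive_modularity_oracle(self):
        g = self.two_triangles()
        best_q, best_partition = max(
            ((manual_modularity(g, p), p) for p in set_partitions(list(g.nodes))),
            key=lambda x: x[0],
        )
        clusters, q = louvain_communities(g, seed=0)
        found = {frozenset(n for n, c in clusters.items() if c == i)
                 for i in set(clusters.values())}
        assert found == {frozenset(p) for p in best_partition}
        assert q == pytest.approx(best_q)

    def test_complete_graph_is_one_community(self):
        clusters, _ = louvain_communities(nx.complete_graph(6), seed=0)
        assert len(set(clusters.values())) == 1

    def test_edgeless_graph_gives_singletons_with_zero_q(self):
        g = nx.empty_graph(5)
        clusters, q = louvain_communities(g, seed=0)
        assert len(set(clusters.values())) == 5
        assert q == 0.0

    def test_partition_at_least_as_good_as_singletons(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        clusters, q = louvain_communities(g, seed=0)
        singleton_q = manual_modularity(g, [[n] for n in g.nodes])
        assert q >= singleton_q - 1e-12


class TestProjectSimilarity:
    def test_identical_projects(self):
        profile = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        sim = project_similarity({"a", "b", "c"}, {"a", "b", "c"}, profile, profile)
        assert (sim.jaccard, sim.overlap, sim.pearson) == (1.0, 1.0, 1.0)

    def test_hand_computed_overlap(self):
        sim = project_similarity({"a", "b"}, {"b", "c"})
        assert sim.jaccard == pytest.approx(1 / 3)
        assert sim.overlap == pytest.approx(1 / 2)

    def test_disjoint_sets_give_zero_and_sentinel(self):
        sim = project_similarity({"a"}, {"b"})
        assert sim.jaccard == 0.0 and sim.overlap == 0.0
        assert np.isnan(sim.pearson)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        shared = [f"p{i}" for i in range(5)]
        pa = pd.Series(rng.normal(size=5), index=shared)
        pb = pd.Series(rng.normal(size=5), index=shared)
        s1 = project_similarity(set(shared) | {"x"}, set(shared) | {"y", "z"}, pa, pb)
        s2 = project_similarity(set(shared) | {"y", "z"}, set(shared) | {"x"}, pb, pa)
        assert s1.jaccard == s2.jaccard
        assert s1.overlap == s2.overlap
        assert s1.pearson == pytest.approx(s2.pearson)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            project_similarity(set(), set())


def brute_betweenness(nodes, edges):
    """All-pairs shortest-path enumeration oracle (endpoints excluded)."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def shortest_paths(s, t):
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
        if t not in dist:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for w in adj[u]:
                if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                    extend(path + [w])

        extend([s])
        return paths

    bc = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = shortest_paths(s, t)
        if not paths:
            continue
        for n in nodes:
            if n in (s, t):
                continue
            bc[n] += sum(1 for p in paths if n in p) / len(paths)
    return bc


def as_property_graph(nodes, edges, label="Protein"):
    g = PropertyGraph()
    for n in nodes:
        g.add_node(str(n), label)
    for u, v in edges:
        g.add_edge(str(u), str(v), "CURATED_INTERACTS_WITH")
    return g


class TestBetweenness:
    def test_middle_of_path_has_unit_pair_count(self):
        g = as_property_graph([0, 1, 2], [(0, 1), (1, 2)])
        bc = betweenness_centrality(g)
        assert bc == {"0": 0.0, "1": 1.0, "2": 0.0}

    def test_star_center_is_maximal(self):
        g = as_property_graph(range(6), [(0, i) for i in range(1, 6)])
        bc = betweenness_centrality(g)
        assert bc["0"] == max(bc.values()) > 0

    def test_matches_bruteforce_on_random_eight_node_graphs(self):
        rng = np.random.default_rng(6)
        for trial in range(15):
            g_nx = nx.gnp_random_graph(8, 0.35, seed=int(rng.integers(1 << 30)))
            g = as_property_graph(g_nx.nodes, g_nx.edges)
            oracle = brute_betweenness([str(n) for n in g_nx.nodes],
                                       [(str(u), str(v)) for u, v in g_nx.edges])
            bc = betweenness_centrality(g)
            for n in oracle:
                assert bc[n] == pytest.approx(oracle[n]), (trial, n)


class TestKnowledgeSummary:
    def star_disease_graph(self, n_diseases=20):
        g = PropertyGraph()
        g.add_node("prot", "Protein")
        for i in range(n_diseases):
            d = f"DIS{i:03d}"
            g.add_node(d, "Disease")
            g.add_edge("prot", d, "ASSOCIATED_WITH")
        return g

    def test_cap_retains_exactly_fifteen_diseases(self):
        summary = betweenness_topk(self.star_disease_graph(20), k_per_label=15)
        assert len(summary.retained["Disease"]) == 15
        # ties (all zero betweenness) resolved by ascending node id
        assert summary.retained["Disease"] == [f"DIS{i:03d}" for i in range(15)]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            betweenness_topk(self.star_disease_graph(3), k_per_label=0)

    def test_single_protein_with_two_diseases_gives_three_nodes(self):
        g = self.star_disease_graph(2)
        summary = build_knowledge_subgraph(g, ["prot"])
        assert len(summary.subgraph) == 3

    def test_hub_drug_connecting_regulated_proteins_ranks_first(self):
        g = PropertyGraph()
        regulated = [f"p{i}" for i in range(6)]
        for p in regulated:
            g.add_node(p, "Protein")
        g.add_node("hub", "Drug")
        g.add_node("minor", "Drug")
        for p in regulated:
            g.add_edge("hub", p, "ACTS_ON", {"action": "inhibition"})
        g.add_edge("minor", regulated[0], "ACTS_ON", {"action": "inhibition"})
        summary = build_knowledge_subgraph(g, regulated)
        assert summary.retained["Drug"][0] == "hub"

    def test_k_one_keeps_one_node_per_label_with_candidates(self):
        g = self.star_disease_graph(5)
        g.add_node("dr", "Drug")
        g.add_edge("dr", "prot", "ACTS_ON", {"action": "inhibition"})
        summary = build_knowledge_subgraph(g, ["prot"], k_per_label=1)
        assert len(summary.retained["Disease"]) == 1
        assert len(summary.retained["Drug"]) == 1

    def test_kinases_enter_via_substrate_edges_only(self):
        g = PropertyGraph()
        for p in ("site", "kinase", "interactor"):
            g.add_node(p, "Protein")
        g.add_edge("site", "kinase", "IS_SUBSTRATE_OF")
        g.add_edge("site", "interactor", "CURATED_INTERACTS_WITH")
        summary = build_knowledge_subgraph(g, ["site"])
        assert "kinase" in summary.subgraph
        assert "interactor" not in summary.subgraph

    def test_empty_regulated_set_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            summary = build_knowledge_subgraph(self.star_disease_graph(3), [])
        assert len(summary.subgraph) == 0

    def test_sankey_edge_list_aggregates_label_pairs(self):
        summary = build_knowledge_subgraph(self.star_disease_graph(4), ["prot"])
        row = summary.sankey.iloc[0]
        assert (row["source_label"], row["target_label"]) == ("Protein", "Disease")
        assert row["weight"] == 4
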