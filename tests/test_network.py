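"""Co-occurrence network construction and the ten topology metrics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from comorbnet.errors import ContractError
from comorbnet.network import (CooccurrenceNetwork, build_network,
                               compare_ad_vs_control, compare_networks_kw,
                               export_graphml, node_metrics, top_pairs,
                               visualization_subnetwork)


def brute_force_metrics(g: nx.Graph) -> pd.DataFrame:
    """Independent oracle: BFS from every node plus explicit enumeration of
    all shortest paths (via networkx) for stress and betweenness."""
    rows = {}
    for comp_nodes in nx.connected_components(g):
        comp = sorted(comp_nodes)
        sub = g.subgraph(comp)
        nc = len(comp)
        spl = dict(nx.all_pairs_shortest_path_length(sub))
        ecc = nx.eccentricity(sub) if nc > 1 else {comp[0]: 0}
        diam = max(ecc.values())
        stress = {v: 0 for v in comp}
        betw = {v: 0.0 for v in comp}
        for s, t in itertools.combinations(comp, 2):
            paths = list(nx.all_shortest_paths(sub, s, t))
            for v in comp:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                stress[v] += through
                betw[v] += through / len(paths)
        norm = (nc - 1) * (nc - 2) / 2
        for v in comp:
            k = g.degree[v]
            aspl = sum(spl[v].values()) / (nc - 1) if nc > 1 else 0.0
            if k > 1:
                js = []
                for m in comp:
                    if m == v:
                        continue
                    shared = len(set(g[v]) & set(g[m]))
                    if shared > 0:
                        js.append(shared + (1 if g.has_edge(v, m) else 0))
                tc = float(np.mean(js)) / k if js else 0.0
            else:
                tc = 0.0
            rows[v] = {
                "degree": k,
                "average_shortest_path_length": aspl,
                "closeness_centrality": 1 / aspl if aspl > 0 else 0.0,
                "eccentricity": float(ecc[v]) if nc > 1 else 0.0,
                "radiality": (diam + 1 - aspl) / diam if diam > 0 else 1.0,
                "stress": float(stress[v]),
                "betweenness_centrality": betw[v] / norm if norm > 0 else 0.0,
                "clustering_coefficient": nx.clustering(g, v),
                "neighborhood_connectivity": (
                    float(np.mean([g.degree[w] for w in g[v]])) if k else 0.0),
                "topological_coefficient": tc,
            }
    return pd.DataFrame(rows).T.loc[sorted(g.nodes)]


@pytest.fixture()
def prevalence_matrix():
    """20-patient matrix with hand-set prevalences around the 5% cut."""
    rows = np.zeros((20, 4), dtype=bool)
    rows[:1, 0] = True       # 5.0% exactly -> excluded (strict >)
    rows[:2, 1] = True       # 10%
    rows[:6, 2] = True       # 30%
    rows[:5, 3] = True       # 25%
    return pd.DataFrame(rows, index=[f"p{i}" for i in range(20)],
                        columns=["at_cut", "rare", "common", "mid"])


def test_strict_threshold_excludes_boundary(prevalence_matrix):
    net = build_network(prevalence_matrix, prevalence_matrix.index)
    assert "at_cut" not in net.nodes
    assert set(net.nodes) == {"rare", "common", "mid"}


def test_edges_match_hand_enumeration(prevalence_matrix):
    net = build_network(prevalence_matrix, prevalence_matrix.index)
    # co-occurrence: rare&common share 2/20 = 10%; mid&common 5/20 = 25%;
    # rare&mid 2/20 = 10%
    assert net.edges[("common", "mid")] == pytest.approx(0.25)
    assert net.edges[("common", "rare")] == pytest.approx(0.10)
    assert set(net.edges) == {("common", "mid"), ("common", "rare"),
                              ("mid", "rare")}
    for (u, v), co in net.edges.items():
        assert co <= min(net.nodes[u], net.nodes[v]) + 1e-12


def test_empty_cohort_errors(prevalence_matrix):
    with pytest.raises(ContractError):
        build_network(prevalence_matrix, [])


def test_threshold_monotonicity(prevalence_matrix):
    low = build_network(prevalence_matrix, prevalence_matrix.index,
                        node_threshold=0.05, edge_threshold=0.05)
    high = build_network(prevalence_matrix, prevalence_matrix.index,
                         node_threshold=0.2, edge_threshold=0.2)
    assert set(high.nodes) <= set(low.nodes)
    assert set(high.edges) <= set(low.edges)


def test_triangle_metric_values():
    metrics = node_metrics(nx.complete_graph(3))
    for _, row in metrics.iterrows():
        assert row["degree"] == 2
        assert row["clustering_coefficient"] == 1.0
        assert row["eccentricity"] == 1.0
        assert row["radiality"] == 1.0
        assert row["stress"] == 0.0
        assert row["betweenness_centrality"] == 0.0
        assert row["neighborhood_connectivity"] == 2.0
        assert row["topological_coefficient"] == 1.0


def test_path_graph_stress_center():
    metrics = node_metrics(nx.path_graph(5))
    assert metrics.loc[2, "stress"] == 4.0


def test_metrics_match_oracle_on_small_graphs():
    graphs = [nx.path_graph(6), nx.cycle_graph(6), nx.star_graph(5),
              nx.barbell_graph(3, 2), nx.complete_bipartite_graph(2, 3),
              nx.lollipop_graph(4, 3)]
    rng = np.random.default_rng(7)
    graphs += [nx.gnp_random_graph(12, 0.25, seed=int(s))
               for s in rng.integers(0, 1000, 5)]
    for g in graphs:
        mine = node_metrics(g)
        oracle = brute_force_metrics(g)[mine.columns]
        assert np.allclose(mine.to_numpy(float), oracle.to_numpy(float),
                           atol=1e-10)


def test_disconnected_graph_conventions():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2)])
    g.add_node(9)  # isolated
    metrics = node_metrics(g)
    iso = metrics.loc[9]
    assert iso["degree"] == 0
    assert iso["closeness_centrality"] == 0.0
    assert iso["eccentricity"] == 0.0
    assert iso["radiality"] == 1.0
    connected = metrics.drop(9)
    assert (connected["eccentricity"]
            >= connected["average_shortest_path_length"]).all()


def test_stress_conservation(rng):
    """Sum of stress over nodes counts every internal vertex of every
    shortest path exactly once."""
    g = nx.gnp_random_graph(10, 0.3, seed=5)
    total = node_metrics(g)["stress"].sum()
    expected = 0
    for comp_nodes in nx.connected_components(g):
        sub = g.subgraph(comp_nodes)
        for s, t in itertools.combinations(sorted(comp_nodes), 2):
            for path in nx.all_shortest_paths(sub, s, t):
                expected += max(0, len(path) - 2)
    assert total == expected


def test_compare_networks_requires_three():
    t = pd.DataFrame({"degree": [1.0, 2.0]})
    with pytest.raises(ContractError):
        compare_networks_kw({"a": t, "b": t}, "degree")


def test_identical_networks_not_significant():
    t = pd.DataFrame({"degree": np.arange(20, dtype=float)})
    h, p, pairs = compare_networks_kw({"a": t, "b": t.copy(), "c": t.copy(),
                                       "d": t.copy()}, "degree")
    assert p > 0.99
    u, p2 = compare_ad_vs_control(t, t.copy(), "degree")
    assert p2 > 0.99


def test_structurally_different_networks_detected():
    star = node_metrics(nx.star_graph(24))
    path = node_metrics(nx.path_graph(25))
    cycle = node_metrics(nx.cycle_graph(25))
    h, p, pairs = compare_networks_kw(
        {"star": star, "path": path, "cycle": cycle}, "degree")
    assert p < 0.05
    assert len(pairs) == 3


def test_top_pairs_ordering_and_truncation():
    net = CooccurrenceNetwork(
        nodes={"a": 0.5, "b": 0.5, "c": 0.5},
        edges={("a", "b"): 0.43, ("a", "c"): 0.40, ("b", "c"): 0.41},
        node_threshold=0.05, edge_threshold=0.05, cohort_size=100)
    ranked = top_pairs(net, k=2)
    assert [co for _, co in ranked] == [0.43, 0.41]
    assert len(top_pairs(net, k=10)) == 3


def test_top_pairs_empty_warns():
    net = CooccurrenceNetwork(nodes={"a": 0.5}, edges={},
                              node_threshold=0.05, edge_threshold=0.05,
                              cohort_size=10)
    with pytest.warns(UserWarning):
        assert top_pairs(net) == []


def test_visualization_threshold_and_roundtrip(tmp_path, prevalence_matrix):
    path = tmp_path / "viz.graphml"
    net = visualization_subnetwork(prevalence_matrix, prevalence_matrix.index,
                                   threshold=0.25, graphml_path=path,
                                   categories={"common": "symptoms"})
    # 25% is excluded (strict), 30% included
    assert set(net.nodes) == {"common"}
    back = nx.read_graphml(path)
    assert nx.is_isomorphic(back, net.graph())
    assert back.nodes["common"]["category"] == "symptoms"
    full = build_network(prevalence_matrix, prevalence_matrix.index)
    assert set(net.nodes) <= set(full.nodes)


def test_graphml_roundtrip_with_edges(tmp_path, prevalence_matrix):
    net = build_network(prevalence_matrix, prevalence_matrix.index)
    path = tmp_path / "net.graphml"
    export_graphml(net, path)
    back = nx.read_graphml(path)
    assert nx.is_isomorphic(back, net.graph())
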