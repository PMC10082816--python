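"""Prevalence-thresholded phenotype co-occurrence networks and topology.

A network is built per (stratum, AD status) cohort: phenotypes shared by
more than ``node_threshold`` of the cohort become nodes, and phenotype
pairs shared by more than ``edge_threshold`` of the cohort become edges
(strict inequalities).  Graphs are simple and unweighted; prevalences are
node/edge attributes, not weights.

Ten per-node topology metrics mirror the classic network-analyzer suite:
degree, average shortest path length, closeness centrality, eccentricity,
radiality, stress, betweenness centrality, clustering coefficient,
neighborhood connectivity and topological coefficient.  Path-based
metrics are computed within each connected component; degenerate-node
conventions are documented on :func:`node_metrics`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, ContractError
from .ranktests import dunn_posthoc, kruskal_wallis, mann_whitney_u

METRIC_NAMES = [
    "degree", "average_shortest_path_length", "closeness_centrality",
    "eccentricity", "radiality", "stress", "betweenness_centrality",
    "clustering_coefficient", "neighborhood_connectivity",
    "topological_coefficient",
]


@dataclass
class CooccurrenceNetwork:
    """Thresholded co-occurrence graph plus its provenance."""

    nodes: dict[str, float]                     # phenotype -> prevalence
    edges: dict[tuple[str, str], float]         # sorted pair -> co-prevalence
    node_threshold: float
    edge_threshold: float
    cohort_size: int
    label: str = ""

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node, prevalence in self.nodes.items():
            g.add_node(node, prevalence=float(prevalence))
        for (u, v), co in self.edges.items():
            g.add_edge(u, v, co_prevalence=float(co))
        return g


def build_network(matrix: pd.DataFrame, cohort_ids,
                  node_threshold: float = 0.05,
                  edge_threshold: float = 0.05,
                  label: str = "") -> CooccurrenceNetwork:
    """Build the co-occurrence network for one cohort.

    Thresholds are strict: a phenotype at exactly the node threshold is
    excluded.  Nodes may be isolated; self-pairs are excluded.  Edge
    endpoints are always nodes because a pair's co-prevalence cannot
    exceed either marginal prevalence.
    """
    cohort_ids = list(cohort_ids)
    if not cohort_ids:
        raise ContractError("empty cohort")
    if not (0 <= node_threshold < 1 and 0 <= edge_threshold < 1):
        raise ConfigError("thresholds must lie in [0, 1)")
    sub = matrix.loc[cohort_ids]
    n = len(sub)
    prevalence = sub.mean(axis=0)
    kept = prevalence.index[prevalence > node_threshold]
    nodes = {p: float(prevalence[p]) for p in sorted(kept)}
    x = sub[sorted(kept)].to_numpy(float)
    co = (x.T @ x) / n
    names = sorted(kept)
    edges = {}
    ii, jj = np.nonzero(np.triu(co, k=1) > edge_threshold)
    for i, j in zip(ii, jj):
        edges[(names[i], names[j])] = float(co[i, j])
    return CooccurrenceNetwork(nodes=nodes, edges=edges,
                               node_threshold=node_threshold,
                               edge_threshold=edge_threshold,
                               cohort_size=n, label=label)


def _bfs_distances_and_counts(adj: list[np.ndarray], n: int):
    """All-pairs shortest-path distances and path counts by BFS per source."""
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        d = np.full(n, -1, dtype=np.int64)
        sig = np.zeros(n)
        d[s] = 0
        sig[s] = 1.0
        queue = [s]
        head = 0
        while head < len(queue):
            v = queue[head]
            head += 1
            for w in adj[v]:
                if d[w] < 0:
                    d[w] = d[v] + 1
                    queue.append(w)
                if d[w] == d[v] + 1:
                    sig[w] += sig[v]
        dist[s] = np.where(d < 0, np.inf, d)
        sigma[s] = sig
    return dist, sigma


def node_metrics(network: CooccurrenceNetwork | nx.Graph) -> pd.DataFrame:
    """The ten per-node topology metrics, one row per node.

    Definitions (unweighted, per connected component):

    * degree — neighbor count.
    * clustering_coefficient — 2e / (k(k-1)) over the neighborhood's edge
      count e, 0 when k < 2.
    * neighborhood_connectivity — mean neighbor degree, 0 when isolated.
    * average_shortest_path_length (aspl) — mean distance to every other
      node of the component; 0 for a singleton component.
    * closeness_centrality — 1 / aspl (0 for singletons).
    * eccentricity — maximum distance within the component (0 for
      singletons).
    * radiality — (diameter + 1 - aspl) / diameter over the component
      diameter; 1 when the component is a singleton or has diameter 0.
    * stress — number of shortest paths between unordered pairs (s, t),
      s != n != t, passing through n (all shortest paths per pair count).
    * betweenness_centrality — sum over pairs of the fraction of shortest
      paths through n, normalized by (Nc-1)(Nc-2)/2 within the component.
    * topological_coefficient — mean over nodes m sharing at least one
      neighbor with n of J(n, m)/k(n), where J = shared neighbors plus 1
      if m is adjacent to n; 0 when k(n) <= 1.
    """
    g = network.graph() if isinstance(network, CooccurrenceNetwork) else network
    names = sorted(g.nodes)
    n = len(names)
    if n == 0:
        return pd.DataFrame(columns=METRIC_NAMES)
    index = {v: i for i, v in enumerate(names)}
    a = np.zeros((n, n), dtype=np.int64)
    for u, v in g.edges:
        a[index[u], index[v]] = 1
        a[index[v], index[u]] = 1
    adj = [np.nonzero(a[i])[0] for i in range(n)]
    degree = a.sum(axis=1)

    dist, sigma = _bfs_distances_and_counts(adj, n)

    clustering = np.zeros(n)
    neigh_conn = np.zeros(n)
    topo = np.zeros(n)
    shared = a @ a  # shared[i, j] = common neighbors of i and j
    for i in range(n):
        k = degree[i]
        nb = adj[i]
        if k >= 1:
            neigh_conn[i] = degree[nb].mean()
        if k >= 2:
            e = a[np.ix_(nb, nb)].sum() / 2
            clustering[i] = 2.0 * e / (k * (k - 1))
        if k > 1:
            partners = np.nonzero(shared[i])[0]
            partners = partners[partners != i]
            if partners.size:
                j_vals = shared[i, partners] + a[i, partners]
                topo[i] = float(np.mean(j_vals / k))

    aspl = np.zeros(n)
    closeness = np.zeros(n)
    eccentricity = np.zeros(n)
    radiality = np.ones(n)
    stress = np.zeros(n)
    betweenness = np.zeros(n)

    finite = np.isfinite(dist)
    seen = np.zeros(n, dtype=bool)
    for i in range(n):
        if seen[i]:
            continue
        comp = np.nonzero(finite[i])[0]
        seen[comp] = True
        nc = comp.size
        if nc == 1:
            continue
        d_sub = dist[np.ix_(comp, comp)]
        s_sub = sigma[np.ix_(comp, comp)]
        aspl_sub = d_sub.sum(axis=1) / (nc - 1)
        ecc_sub = d_sub.max(axis=1)
        diameter = ecc_sub.max()
        aspl[comp] = aspl_sub
        closeness[comp] = 1.0 / aspl_sub
        eccentricity[comp] = ecc_sub
        if diameter > 0:
            radiality[comp] = (diameter + 1.0 - aspl_sub) / diameter
        pair_norm = (nc - 1) * (nc - 2) / 2.0
        for vi in range(nc):
            on_path = (d_sub[:, vi][:, None] + d_sub[vi, :][None, :]
                       == d_sub)
            on_path[vi, :] = False
            on_path[:, vi] = False
            np.fill_diagonal(on_path, False)
            w = np.outer(s_sub[:, vi], s_sub[vi, :])
            stress[comp[vi]] = (w * on_path).sum() / 2.0
            if pair_norm > 0:
                with np.errstate(invalid="ignore", divide="ignore"):
                    frac = np.where(on_path, w / s_sub, 0.0)
                betweenness[comp[vi]] = frac.sum() / 2.0 / pair_norm

    return pd.DataFrame({
        "degree": degree,
        "average_shortest_path_length": aspl,
        "closeness_centrality": closeness,
        "eccentricity": eccentricity,
        "radiality": radiality,
        "stress": stress,
        "betweenness_centrality": betweenness,
        "clustering_coefficient": clustering,
        "neighborhood_connectivity": neigh_conn,
        "topological_coefficient": topo,
    }, index=pd.Index(names, name="phenotype"))


def compare_networks_kw(metric_tables: dict[str, pd.DataFrame],
                        metric_name: str):
    """Kruskal-Wallis comparison of one node-level metric across three or
    more networks, with Dunn's Bonferroni-corrected post-hoc pairs."""
    if len(metric_tables) < 3:
        raise ContractError("need at least 3 networks to compare")
    values, labels = [], []
    for label in sorted(metric_tables):
        table = metric_tables[label]
        if metric_name not in table.columns:
            raise ContractError(f"metric {metric_name!r} missing in {label!r}")
        values.append(table[metric_name].to_numpy(float))
        labels.append(np.repeat(label, len(table)))
    values = np.concatenate(values)
    labels = np.concatenate(labels)
    h, p = kruskal_wallis(values, labels)
    pairs = dunn_posthoc(values, labels)
    return h, p, pairs


def compare_ad_vs_control(metric_table_ad: pd.DataFrame,
                          metric_table_ctrl: pd.DataFrame,
                          metric_name: str) -> tuple[float, float]:
    """Mann-Whitney U on node-level metric values, AD vs control network."""
    for name, table in (("AD", metric_table_ad), ("control", metric_table_ctrl)):
        if table.empty:
            raise ContractError(f"{name} metric table is empty")
        if metric_name not in table.columns:
            raise ContractError(f"metric {metric_name!r} missing in {name}")
    return mann_whitney_u(metric_table_ad[metric_name].to_numpy(float),
                          metric_table_ctrl[metric_name].to_numpy(float))


def top_pairs(network: CooccurrenceNetwork, k: int = 10):
    """Top-k edges by co-prevalence (descending; ties lexicographic)."""
    if not network.edges:
        warnings.warn("network has no edges", stacklevel=2)
        return []
    ranked = sorted(network.edges.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(pair, co) for pair, co in ranked[:k]]


def visualization_subnetwork(matrix: pd.DataFrame, cohort_ids,
                             threshold: float = 0.25, label: str = "",
                             categories: dict[str, str] | None = None,
                             graphml_path: str | Path | None = None
                             ) -> CooccurrenceNetwork:
    """Rebuild the network at the visualization threshold (node and edge)
    and optionally export GraphML with prevalence, co-prevalence and
    phecode-category attributes."""
    network = build_network(matrix, cohort_ids, node_threshold=threshold,
                            edge_threshold=threshold, label=label)
    if graphml_path is not None:
        export_graphml(network, graphml_path, categories=categories)
    return network


def export_graphml(network: CooccurrenceNetwork, path: str | Path,
                   categories: dict[str, str] | None = None) -> None:
    g = network.graph()
    if categories:
        for node in g.nodes:
            g.nodes[node]["category"] = categories.get(node, "")
    nx.write_graphml(g, str(path))
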