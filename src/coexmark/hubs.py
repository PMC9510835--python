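"""Twelve node-centrality scores and the consensus hub rule.

The measures mirror the topological scores of the cytoHubba ranking
toolkit: Degree, Betweenness, harmonic Closeness, reciprocal Eccentricity,
Radiality, Stress, Clustering Coefficient, MNC (maximum neighborhood
component), DMNC (density of MNC, exponent 1.7), MCC (maximal clique
centrality), BottleNeck and EPC (edge percolated connectivity, Monte
Carlo with a fixed edge-keep probability). Every measure is oriented so
that larger means more central, which makes the "top 25% of each ranking"
rule uniform; the consensus rule flags a node as a hub when it appears in
more than four of the twelve top lists.

Disconnected graphs are handled throughout: distances are taken within
components, unreachable pairs contribute 0 to harmonic sums.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ALL_MEASURES",
    "HubSelection",
    "compute_centralities",
    "top_fraction",
    "consensus_hubs",
    "graph_from_edges",
]

ALL_MEASURES = [
    "Degree",
    "Betweenness",
    "Closeness",
    "Eccentricity",
    "Radiality",
    "Stress",
    "ClusteringCoefficient",
    "MNC",
    "DMNC",
    "MCC",
    "BottleNeck",
    "EPC",
]


@dataclass
class HubSelection:
    top_lists: dict[str, list]  # measure -> ordered top-fraction node list
    occurrence: pd.Series  # node -> number of top lists containing it
    hubs: list  # nodes with occurrence >= min_count
    fraction: float
    min_count: int


def graph_from_edges(edges: pd.DataFrame, nodes: list | None = None) -> nx.Graph:
    """Build a simple undirected graph from a canonical edge table."""
    graph = nx.Graph()
    if nodes is not None:
        graph.add_nodes_from(nodes)
    graph.add_edges_from(zip(edges["node_a"], edges["node_b"]))
    graph.remove_edges_from(nx.selfloop_edges(graph))
    return graph


def _shortest_path_data(graph: nx.Graph, source):
    """BFS distances and shortest-path counts from ``source``."""
    dist = {source: 0}
    sigma = {source: 1.0}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0.0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        queue = nxt
    return dist, sigma


def _stress(graph: nx.Graph, nodes: list) -> dict:
    """Stress centrality: number of shortest s–t paths passing through v."""
    stress = {v: 0.0 for v in nodes}
    data = {s: _shortest_path_data(graph, s) for s in nodes}
    for i, s in enumerate(nodes):
        dist_s, sig_s = data[s]
        for t in nodes[i + 1 :]:
            if t not in dist_s:
                continue
            d_st = dist_s[t]
            dist_t, sig_t = data[t]
            for v in dist_s:
                if v == s or v == t:
                    continue
                if dist_s[v] + dist_t.get(v, math.inf) == d_st:
                    stress[v] += sig_s[v] * sig_t[v]
    return stress


def _bottleneck(graph: nx.Graph, nodes: list) -> dict:
    """BottleNeck: for how many BFS tree roots is v a large-subtree gate.

    The shortest-path tree from each root is made deterministic by taking
    each node's parent to be its smallest-id neighbor at depth − 1; v
    scores a point for root s when v ≠ s and the subtree rooted at v holds
    more than n/4 of the root's component.
    """
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        dist, _ = _shortest_path_data(graph, s)
        comp = sorted(dist, key=str)
        n_comp = len(comp)
        if n_comp < 2:
            continue
        children: dict = {v: [] for v in comp}
        for v in comp:
            if v == s:
                continue
            parent = min(
                (u for u in graph.neighbors(v) if dist.get(u, -2) == dist[v] - 1),
                key=str,
            )
            children[parent].append(v)
        subtree = {}
        for v in sorted(comp, key=lambda u: -dist[u]):  # leaves first
            subtree[v] = 1 + sum(subtree[c] for c in children[v])
        for v in comp:
            if v != s and subtree[v] > n_comp / 4.0:
                score[v] += 1.0
    return score


def _mcc(graph: nx.Graph, nodes: list) -> dict:
    """Maximal clique centrality: Σ over maximal cliques containing v of (|C|−1)!."""
    mcc = {v: 0.0 for v in nodes}
    for clique in nx.find_cliques(graph):
        contribution = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += contribution
    return mcc


def _mnc_dmnc(graph: nx.Graph, v) -> tuple[float, float]:
    neighbors = list(graph.neighbors(v))
    if not neighbors:
        return 0.0, 0.0
    sub = graph.subgraph(neighbors)
    best = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(map(str, c))))
    m = sub.subgraph(best)
    n_m = m.number_of_nodes()
    mnc = float(n_m)
    dmnc = m.number_of_edges() / n_m**1.7 if n_m > 1 else 0.0
    return mnc, float(dmnc)


def _epc(graph: nx.Graph, nodes: list, trials: int, keep_prob: float, rng) -> dict:
    """Edge percolated connectivity: expected reachable-set size of v.

    Each trial keeps every edge independently with probability
    ``keep_prob``; EPC(v) averages the number of other nodes still
    connected to v.
    """
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges() if a in index and b in index]
    n = len(nodes)
    counts = np.zeros(n)
    for _ in range(trials):
        keep = rng.random(len(edges)) < keep_prob
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for (a, b), k in zip(edges, keep):
            if k:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
        roots = np.fromiter((find(i) for i in range(n)), dtype=int, count=n)
        _, inverse, sizes = np.unique(roots, return_inverse=True, return_counts=True)
        counts += sizes[inverse] - 1
    return {v: counts[index[v]] / trials for v in nodes}


def compute_centralities(
    graph: nx.Graph,
    measures: list[str] | None = None,
    epc_trials: int = 1000,
    epc_keep_prob: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every node on the requested centrality measures.

    Returns a node × measure DataFrame (rows sorted by node id). All
    measures are deterministic except EPC, which is a seeded Monte Carlo
    average.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    measures = list(measures) if measures is not None else list(ALL_MEASURES)
    unknown = [m for m in measures if m not in ALL_MEASURES]
    if unknown:
        raise ValueError(f"unknown measures: {unknown}")
    nodes = sorted(graph.nodes(), key=str)
    table = pd.DataFrame(index=pd.Index(nodes, name="node"))

    components = list(nx.connected_components(graph))
    comp_of = {v: comp for comp in components for v in comp}
    sp_cache: dict = {}

    def dists_from(v):
        if v not in sp_cache:
            sp_cache[v] = _shortest_path_data(graph, v)[0]
        return sp_cache[v]

    for measure in measures:
        if measure == "Degree":
            table[measure] = [float(graph.degree(v)) for v in nodes]
        elif measure == "Betweenness":
            bc = nx.betweenness_centrality(graph, normalized=False)
            table[measure] = [bc[v] for v in nodes]
        elif measure == "Closeness":
            table[measure] = [
                sum(1.0 / d for u, d in dists_from(v).items() if u != v) for v in nodes
            ]
        elif measure == "Eccentricity":
            scores = []
            for v in nodes:
                ecc = max(dists_from(v).values())
                scores.append(1.0 / ecc if ecc > 0 else 0.0)
            table[measure] = scores
        elif measure == "Radiality":
            scores = []
            for v in nodes:
                comp = comp_of[v]
                n_comp = len(comp)
                if n_comp < 2:
                    scores.append(0.0)
                    continue
                diameter = max(
                    max(dists_from(u).values()) for u in comp
                )
                dist = dists_from(v)
                scores.append(
                    sum(diameter + 1 - dist[u] for u in comp if u != v) / (n_comp - 1)
                )
            table[measure] = scores
        elif measure == "Stress":
            st = _stress(graph, nodes)
            table[measure] = [st[v] for v in nodes]
        elif measure == "ClusteringCoefficient":
            cc = nx.clustering(graph)
            table[measure] = [cc[v] for v in nodes]
        elif measure in ("MNC", "DMNC"):
            if measure in table.columns:
                continue
            pairs = [_mnc_dmnc(graph, v) for v in nodes]
            if "MNC" in measures:
                table["MNC"] = [p[0] for p in pairs]
            if "DMNC" in measures:
                table["DMNC"] = [p[1] for p in pairs]
        elif measure == "MCC":
            mcc = _mcc(graph, nodes)
            table[measure] = [mcc[v] for v in nodes]
        elif measure == "BottleNeck":
            bn = _bottleneck(graph, nodes)
            table[measure] = [bn[v] for v in nodes]
        elif measure == "EPC":
            rng = np.random.default_rng(seed)
            epc = _epc(graph, nodes, epc_trials, epc_keep_prob, rng)
            table[measure] = [epc[v] for v in nodes]
    return table[measures]


def top_fraction(scores: pd.Series, fraction: float = 0.25) -> list:
    """Top ceil(fraction·n) nodes by descending score, ties by node id."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(scores) == 0:
        raise ValueError("empty score map")
    n_keep = math.ceil(fraction * len(scores))
    order = sorted(scores.index, key=lambda v: (-scores[v], str(v)))
    return order[:n_keep]


def consensus_hubs(
    table: pd.DataFrame, fraction: float = 0.25, min_count: int = 5
) -> HubSelection:
    """Consensus hub rule: in the top ``fraction`` of ≥ ``min_count`` measures.

    ``min_count`` = 5 implements "appearing in more than 4 of the 12
    rankings". Output is independent of the measure column order.
    """
    if table.shape[1] < 1:
        raise ValueError("need at least one computed measure")
    if min_count > table.shape[1]:
        warnings.warn(
            f"min_count {min_count} exceeds number of measures {table.shape[1]}: no hubs",
            stacklevel=2,
        )
    top_lists = {m: top_fraction(table[m], fraction) for m in table.columns}
    occurrence = pd.Series(0, index=table.index, dtype=int)
    for members in top_lists.values():
        occurrence[members] += 1
    hubs = sorted(occurrence.index[occurrence >= min_count], key=str)
    return HubSelection(top_lists, occurrence, hubs, fraction, min_count)
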