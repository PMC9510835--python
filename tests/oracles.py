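"""Independent brute-force reference implementations for the test suite.

Everything here is deliberately naive (path enumeration, triple loops,
exhaustive subsets) and shares no code with the package, so agreement on
small instances is evidence of correctness, not of shared bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# ---------------------------------------------------------------------------
# graphs as (sorted node list, set of frozenset edges)
# ---------------------------------------------------------------------------


def graph_to_plain(graph) -> tuple[list, set]:
    nodes = sorted(graph.nodes(), key=str)
    edges = {frozenset((a, b)) for a, b in graph.edges() if a != b}
    return nodes, edges


def _adjacent(edges: set, a, b) -> bool:
    return frozenset((a, b)) in edges


def _neighbors(nodes, edges, v) -> list:
    return [u for u in nodes if u != v and _adjacent(edges, u, v)]


def all_simple_paths(nodes, edges, s, t):
    """Every simple s→t path, by exhaustive depth-first enumeration."""
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for u in _neighbors(nodes, edges, last):
            if u not in path:
                path.append(u)
                extend(path)
                path.pop()

    extend([s])
    return paths


def shortest_paths(nodes, edges, s, t):
    paths = all_simple_paths(nodes, edges, s, t)
    if not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def distances_from(nodes, edges, s) -> dict:
    out = {}
    for t in nodes:
        if t == s:
            out[t] = 0
            continue
        sp = shortest_paths(nodes, edges, s, t)
        if sp:
            out[t] = len(sp[0]) - 1
    return out


def components(nodes, edges) -> list[set]:
    comps, seen = [], set()
    for v in nodes:
        if v in seen:
            continue
        comp = {u for u, _ in distances_from(nodes, edges, v).items()}
        comps.append(comp)
        seen |= comp
    return comps


def brute_centralities(graph) -> dict[str, dict]:
    """The 11 deterministic centrality measures, from first principles."""
    nodes, edges = graph_to_plain(graph)
    comp_of = {}
    for comp in components(nodes, edges):
        for v in comp:
            comp_of[v] = comp
    dists = {s: distances_from(nodes, edges, s) for s in nodes}

    out: dict[str, dict] = {m: {} for m in (
        "Degree", "Betweenness", "Closeness", "Eccentricity", "Radiality",
        "Stress", "ClusteringCoefficient", "MNC", "DMNC", "MCC", "BottleNeck",
    )}
    for v in nodes:
        nb = _neighbors(nodes, edges, v)
        out["Degree"][v] = float(len(nb))
        out["Closeness"][v] = sum(1.0 / d for u, d in dists[v].items() if u != v)
        ecc = max(dists[v].values())
        out["Eccentricity"][v] = 1.0 / ecc if ecc > 0 else 0.0
        comp = comp_of[v]
        if len(comp) < 2:
            out["Radiality"][v] = 0.0
        else:
            diam = max(max(dists[u][w] for w in comp) for u in comp)
            out["Radiality"][v] = sum(
                diam + 1 - dists[v][u] for u in comp if u != v
            ) / (len(comp) - 1)
        # clustering coefficient
        if len(nb) < 2:
            out["ClusteringCoefficient"][v] = 0.0
        else:
            links = sum(
                1 for a, b in itertools.combinations(nb, 2) if _adjacent(edges, a, b)
            )
            out["ClusteringCoefficient"][v] = 2.0 * links / (len(nb) * (len(nb) - 1))
        # MNC / DMNC on the neighbor-induced subgraph
        sub_edges = {e for e in edges if e <= set(nb)}
        sub_comps = components(nb, sub_edges) if nb else []
        if sub_comps:
            best = max(sub_comps, key=lambda c: (len(c), sorted(map(str, c))))
            m_edges = sum(1 for e in sub_edges if e <= best)
            out["MNC"][v] = float(len(best))
            out["DMNC"][v] = m_edges / len(best) ** 1.7 if len(best) > 1 else 0.0
        else:
            out["MNC"][v], out["DMNC"][v] = 0.0, 0.0

    # betweenness and stress from enumerated shortest paths
    for v in nodes:
        bet = stress = 0.0
        for s, t in itertools.combinations(nodes, 2):
            if v in (s, t):
                continue
            sp = shortest_paths(nodes, edges, s, t)
            if not sp:
                continue
            through = sum(1 for p in sp if v in p)
            stress += through
            bet += through / len(sp)
        out["Betweenness"][v] = bet
        out["Stress"][v] = stress

    # MCC from exhaustive maximal-clique enumeration
    for v in nodes:
        out["MCC"][v] = 0.0
    for size in range(1, len(nodes) + 1):
        for cand in itertools.combinations(nodes, size):
            if any(not _adjacent(edges, a, b) for a, b in itertools.combinations(cand, 2)):
                continue
            cset = set(cand)
            if any(
                all(_adjacent(edges, u, w) for w in cand)
                for u in nodes
                if u not in cset
            ):
                continue  # extendable, not maximal
            for v in cand:
                out["MCC"][v] += math.factorial(size - 1)

    # BottleNeck with the deterministic smallest-parent-id BFS tree
    for v in nodes:
        out["BottleNeck"][v] = 0.0
    for s in nodes:
        dist = dists[s]
        comp = [v for v in nodes if v in dist]
        n_comp = len(comp)
        if n_comp < 2:
            continue
        parent = {}
        for v in comp:
            if v == s:
                continue
            parent[v] = min(
                (u for u in _neighbors(nodes, edges, v) if dist.get(u, -2) == dist[v] - 1),
                key=str,
            )

        def subtree_size(v) -> int:
            return 1 + sum(subtree_size(c) for c in parent if parent[c] == v)

        for v in comp:
            if v != s and subtree_size(v) > n_comp / 4.0:
                out["BottleNeck"][v] += 1.0
    return out


def exact_epc(graph, keep_prob: float) -> dict:
    """Exact expected percolated connectivity by edge-subset enumeration."""
    nodes, edges = graph_to_plain(graph)
    edge_list = sorted(edges, key=lambda e: sorted(map(str, e)))
    m = len(edge_list)
    expected = {v: 0.0 for v in nodes}
    for mask in range(2**m):
        kept = {edge_list[i] for i in range(m) if mask >> i & 1}
        prob = keep_prob ** len(kept) * (1 - keep_prob) ** (m - len(kept))
        for comp in components(nodes, kept):
            for v in comp:
                expected[v] += prob * (len(comp) - 1)
    return expected


# ---------------------------------------------------------------------------
# numeric oracles
# ---------------------------------------------------------------------------


def brute_tom(adj: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    n = adj.shape[0]
    a = adj.copy()
    for i in range(n):
        a[i, i] = 0.0
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
    return tom


def brute_bh(p: list[float]) -> list[float]:
    """Double-loop Benjamini–Hochberg: adj_i = min over j with p_j >= p_i."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for rank_pos2, j in enumerate(order, start=1):
            if rank_pos2 >= rank_pos:
                candidates.append(min(1.0, p[j] * m / rank_pos2))
        adj[i] = min(candidates)
    return adj


def brute_auc(scores, labels) -> float:
    """Exhaustive pairwise comparison with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def brute_es(order: list[str], scores: dict[str, float], members: set, weight: float):
    """Step-by-step enrichment-score walk."""
    n = len(order)
    hits = [g in members for g in order]
    n_hits = sum(hits)
    denom_hit = sum(abs(scores[g]) ** weight for g, h in zip(order, hits) if h)
    walk, total = [], 0.0
    for g, h in zip(order, hits):
        if h:
            total += (abs(scores[g]) ** weight / denom_hit) if denom_hit > 0 else 1.0 / n_hits
        else:
            total -= 1.0 / (n - n_hits)
        walk.append(total)
    extremum = max(walk, key=abs)
    return extremum, walk
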