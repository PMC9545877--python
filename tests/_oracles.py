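"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the implementation's algorithms: betweenness by
exhaustive simple-path enumeration, clique percolation by direct subset
enumeration, and model search by exhaustive BIC evaluation over all edge
sets.
"""

from itertools import combinations

import networkx as nx
import numpy as np

from symptomnet import constrained_mle


def brute_betweenness(weights: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Betweenness by enumerating all simple paths of every node pair."""
    p = weights.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if weights[i, j] != 0:
                g.add_edge(i, j, length=1.0 / abs(weights[i, j]))
    bc = np.zeros(p)
    for s, t in combinations(range(p), 2):
        paths = []
        try:
            for path in nx.all_simple_paths(g, s, t):
                length = sum(
                    g.edges[path[a], path[a + 1]]["length"] for a in range(len(path) - 1)
                )
                paths.append((length, path))
        except nx.NodeNotFound:
            continue
        if not paths:
            continue
        best = min(pl for pl, _ in paths)
        geodesics = [path for pl, path in paths if pl <= best + tol]
        for path in geodesics:
            for node in path[1:-1]:
                bc[node] += 1.0 / len(geodesics)
    return bc


def naive_percolation(weights: np.ndarray, k: int, threshold: float):
    """Clique percolation by direct subset enumeration (p <= ~10)."""
    p = weights.shape[0]
    cliques = []
    for sub in combinations(range(p), k):
        ws = [abs(weights[a, b]) for a, b in combinations(sub, 2)]
        if all(w > 0 for w in ws):
            intensity = float(np.exp(np.mean(np.log(ws))))
            if intensity >= threshold:
                cliques.append(frozenset(sub))
    g = nx.Graph()
    g.add_nodes_from(range(len(cliques)))
    for a in range(len(cliques)):
        for b in range(a + 1, len(cliques)):
            if len(cliques[a] & cliques[b]) == k - 1:
                g.add_edge(a, b)
    communities = set()
    for comp in nx.connected_components(g):
        nodes = frozenset().union(*(cliques[c] for c in comp))
        communities.add(nodes)
    return communities


def exhaustive_bic_search(S: np.ndarray, n: int):
    """BIC of the constrained MLE for every edge set of a small graph."""
    p = S.shape[0]
    pairs = list(combinations(range(p), 2))
    results = {}
    for mask in range(2 ** len(pairs)):
        edges = frozenset(pairs[b] for b in range(len(pairs)) if mask >> b & 1)
        fit = constrained_mle(S, edges, n=n)
        results[edges] = fit.bic
    return results
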