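"""Centrality indices for weighted signed symptom networks.

Expected influence keeps edge signs (the signed sum of incident weights);
closeness and betweenness operate on shortest paths with edge length
1/|weight|, the standard convention for partial-correlation networks, and
are therefore invariant to flipping every sign. Betweenness uses Brandes
accumulation with fractional credit for tied geodesics (ties detected with
an absolute tolerance of 1e-9 on path length).
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .network import SymptomNetwork

TIE_TOL = 1e-9


def expected_influence(net: SymptomNetwork) -> np.ndarray:
    """One-step expected influence: EI(i) = sum_j w_ij (signed)."""
    return net.weights.sum(axis=1)


def _length_matrix(net: SymptomNetwork) -> csr_matrix:
    with np.errstate(divide="ignore"):
        lengths = np.where(net.weights != 0.0, 1.0 / np.abs(net.weights), 0.0)
    return csr_matrix(lengths)


def node_distances(net: SymptomNetwork) -> np.ndarray:
    """All-pairs shortest-path lengths on edge lengths 1/|w| (inf if unreachable)."""
    if net.p == 0:
        return np.zeros((0, 0))
    return dijkstra(_length_matrix(net), directed=False)


def is_connected(net: SymptomNetwork) -> bool:
    n_comp, _ = connected_components(_length_matrix(net), directed=False)
    return n_comp <= 1


def closeness(net: SymptomNetwork) -> np.ndarray:
    """Closeness (p-1)/sum_j d(i,j), computed within connected components.

    On a disconnected network each node's closeness uses only its own
    component ((|C|-1)/sum of within-component distances) and a warning is
    emitted; isolated nodes get closeness 0.
    """
    p = net.p
    D = node_distances(net)
    n_comp, labels = connected_components(_length_matrix(net), directed=False)
    if n_comp > 1:
        warnings.warn(
            f"network is disconnected ({n_comp} components); closeness computed "
            "within components", stacklevel=2,
        )
    out = np.zeros(p)
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        out[idx] = (idx.size - 1) / sub.sum(axis=1)
    return out


def betweenness(net: SymptomNetwork, tie_tol: float = TIE_TOL) -> np.ndarray:
    """Shortest-path betweenness with fractional credit for tied geodesics.

    Returns, for each node i, the sum over unordered pairs (s, t) with
    s != i != t of the fraction of shortest s-t paths through i.
    """
    p = net.p
    W = np.abs(net.weights)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(p)]
    for i in range(p):
        for j in range(p):
            if i != j and W[i, j] > 0.0:
                adj[i].append((j, 1.0 / W[i, j]))
    bc = np.zeros(p)
    for s in range(p):
        dist = np.full(p, np.inf)
        sigma = np.zeros(p)
        preds: list[list[int]] = [[] for _ in range(p)]
        dist[s] = 0.0
        sigma[s] = 1.0
        settled_order: list[int] = []
        done = np.zeros(p, dtype=bool)
        heap = [(0.0, s)]
        while heap:
            d, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            settled_order.append(u)
            for v, length in adj[u]:
                nd = dist[u] + length
                if nd < dist[v] - tie_tol:
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (nd, v))
                elif abs(nd - dist[v]) <= tie_tol and not done[v]:
                    if u not in preds[v]:
                        sigma[v] += sigma[u]
                        preds[v].append(u)
        delta = np.zeros(p)
        for u in reversed(settled_order):
            for v in preds[u]:
                delta[v] += sigma[v] / sigma[u] * (1.0 + delta[u])
            if u != s:
                bc[u] += delta[u]
    return bc / 2.0  # each unordered pair counted from both endpoints


def standardize(values: np.ndarray) -> np.ndarray:
    """z-scores with the sample (n-1) standard deviation."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least two values to standardize")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


INDICES = {
    "expected_influence": expected_influence,
    "closeness": closeness,
    "betweenness": betweenness,
}


def centrality_table(net: SymptomNetwork) -> pd.DataFrame:
    """Raw, standardized and rank columns for the three indices.

    Ranks are 1 = highest value of the index.
    """
    cols: dict[str, np.ndarray] = {}
    for name, fn in INDICES.items():
        raw = fn(net)
        cols[f"{name}_raw"] = raw
        cols[f"{name}_z"] = standardize(raw)
    df = pd.DataFrame(cols, index=net.item_ids)
    for name in INDICES:
        df[f"{name}_rank"] = (
            df[f"{name}_raw"].rank(ascending=False, method="min").astype(int)
        )
    return df
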