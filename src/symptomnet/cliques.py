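"""Weighted clique percolation with intensity thresholding.

Communities are built from k-cliques (fully connected k-node subsets of the
nonzero-edge skeleton) whose *intensity* — the geometric mean of the
absolute weights of their k(k-1)/2 edges — reaches a threshold I. Retained
cliques sharing k-1 nodes are adjacent; communities are the node unions of
the connected components of this clique graph. Nodes may sit in several
communities or in none.

Intensity uses absolute weights: a negative edge inside an otherwise strong
clique contributes its magnitude, so mixed-sign cliques can percolate.

``parameter_search`` scores a (k, I) grid against a permutation null that
shuffles the nonzero weights over the fixed edge skeleton, so it tests how
the weights organize on the topology rather than the topology itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .network import SymptomNetwork
from .simulate import child_rng

_STREAM_PERMUTE = 7


@dataclass
class CliqueCommunitySolution:
    k: int
    intensity_threshold: float
    communities: list[frozenset]          # of item_ids; overlap allowed
    unassigned: frozenset                 # item_ids in no community
    clique_list: list[tuple[tuple, float]] = field(repr=False)  # retained cliques

    @property
    def n_communities(self) -> int:
        return len(self.communities)


def enumerate_cliques(net: SymptomNetwork, k: int) -> list[tuple[int, ...]]:
    """All k-cliques of the nonzero-edge skeleton, as sorted index tuples."""
    if not 3 <= k <= net.p:
        raise ValueError(f"k must be in [3, p]; got k={k}, p={net.p}")
    g = nx.Graph()
    g.add_nodes_from(range(net.p))
    iu, ju = np.nonzero(np.triu(net.weights, 1))
    g.add_edges_from(zip(iu.tolist(), ju.tolist()))
    seen: set[tuple[int, ...]] = set()
    for maximal in nx.find_cliques(g):
        if len(maximal) < k:
            continue
        for sub in combinations(sorted(maximal), k):
            seen.add(sub)
    return sorted(seen)


def clique_intensity(net: SymptomNetwork, clique) -> float:
    """Geometric mean of the absolute weights of the clique's edges."""
    idx = [c if isinstance(c, (int, np.integer)) else net.index_of(c) for c in clique]
    logs = []
    for a, b in combinations(idx, 2):
        w = abs(net.weights[a, b])
        if w == 0.0:
            raise ValueError(
                f"pair ({net.item_ids[a]}, {net.item_ids[b]}) has zero weight; "
                "not a clique"
            )
        logs.append(np.log(w))
    return float(np.exp(np.mean(logs)))


def _clique_adjacency(cliques: list[tuple[int, ...]], k: int) -> list[tuple[int, int]]:
    """Pairs of clique indices sharing k-1 nodes."""
    sets = [frozenset(c) for c in cliques]
    pairs = []
    for a in range(len(sets)):
        for b in range(a + 1, len(sets)):
            if len(sets[a] & sets[b]) == k - 1:
                pairs.append((a, b))
    return pairs


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def percolate(net: SymptomNetwork, k: int, intensity_threshold: float) -> CliqueCommunitySolution:
    """Clique percolation at one (k, I): retain, chain, union."""
    if intensity_threshold < 0:
        raise ValueError("intensity threshold must be >= 0")
    cliques = enumerate_cliques(net, k)
    intensities = np.array([clique_intensity(net, c) for c in cliques])
    keep = np.flatnonzero(intensities >= intensity_threshold)
    kept = [cliques[i] for i in keep]
    uf = _UnionFind(len(kept))
    for a, b in _clique_adjacency(kept, k):
        uf.union(a, b)
    groups: dict[int, set[int]] = {}
    for ci, cl in enumerate(kept):
        groups.setdefault(uf.find(ci), set()).update(cl)
    ids = net.item_ids
    communities = sorted(
        (frozenset(ids[i] for i in g) for g in groups.values()),
        key=lambda c: (-len(c), sorted(c)),
    )
    covered = set().union(*communities) if communities else set()
    unassigned = frozenset(i for i in ids if i not in covered)
    clique_list = [
        (tuple(ids[i] for i in cliques[ci]), float(intensities[ci])) for ci in keep
    ]
    return CliqueCommunitySolution(
        k=k,
        intensity_threshold=float(intensity_threshold),
        communities=communities,
        unassigned=unassigned,
        clique_list=clique_list,
    )


def parameter_search(
    net: SymptomNetwork,
    k_range=range(3, 7),
    intensity_grid: np.ndarray | None = None,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-based diagnostics over a (k, I) grid.

    For each (k, I) the observed community count is compared with its
    distribution under ``n_permutations`` null networks obtained by
    shuffling the nonzero weights over the fixed edge skeleton. The table
    is sorted by the z-score of the observed count against the null (ties:
    larger observed count, then smaller k, then larger I); the full grid is
    returned so users can pick a solution manually.
    """
    if intensity_grid is None:
        intensity_grid = np.round(np.arange(0.40, 0.01 - 1e-9, -0.005), 3)
    intensity_grid = np.asarray(sorted(set(np.asarray(intensity_grid, float))))[::-1]
    if len(intensity_grid) == 0 or len(list(k_range)) == 0:
        raise ValueError("empty (k, I) grid")
    rng = child_rng(seed, _STREAM_PERMUTE)
    iu = np.triu_indices(net.p, 1)
    w_off = net.weights[iu]
    nz = np.flatnonzero(w_off)
    rows = []
    for k in k_range:
        cliques = enumerate_cliques(net, k)
        if not cliques:
            for I in intensity_grid:
                rows.append((k, float(I), 0, 0.0, 0.0, 0.0))
            continue
        n_edges_per = k * (k - 1) // 2
        # clique x nonzero-edge incidence (on the upper-triangle edge list)
        edge_index = {(int(i), int(j)): e for e, (i, j) in enumerate(zip(*iu))}
        inc = np.zeros((len(cliques), len(w_off)))
        for ci, cl in enumerate(cliques):
            for a, b in combinations(cl, 2):
                inc[ci, edge_index[(a, b)]] = 1.0
        log_abs = np.zeros_like(w_off)
        log_abs[nz] = np.log(np.abs(w_off[nz]))
        adj_pairs = _clique_adjacency(cliques, k)

        def counts_for(log_w: np.ndarray) -> np.ndarray:
            """Community counts at every I (descending grid), incremental."""
            inten = np.exp(inc @ log_w / n_edges_per)
            order = np.argsort(-inten)  # strongest cliques first
            uf = _UnionFind(len(cliques))
            active = np.zeros(len(cliques), dtype=bool)
            nbrs: dict[int, list[int]] = {}
            for a, b in adj_pairs:
                nbrs.setdefault(a, []).append(b)
                nbrs.setdefault(b, []).append(a)
            counts = np.empty(len(intensity_grid), dtype=int)
            n_comp = 0
            pos = 0
            for gi, I in enumerate(intensity_grid):
                while pos < len(order) and inten[order[pos]] >= I:
                    c = order[pos]
                    active[c] = True
                    n_comp += 1
                    for d in nbrs.get(c, []):
                        if active[d] and uf.union(c, d):
                            n_comp -= 1
                    pos += 1
                counts[gi] = n_comp
            return counts

        obs = counts_for(log_abs)
        null = np.empty((n_permutations, len(intensity_grid)), dtype=int)
        for b in range(n_permutations):
            perm = log_abs.copy()
            perm[nz] = perm[rng.permutation(nz)]
            null[b] = counts_for(perm)
        mean = null.mean(axis=0)
        sd = null.std(axis=0)
        z = (obs - mean) / np.where(sd > 0, sd, np.inf)
        for gi, I in enumerate(intensity_grid):
            rows.append((int(k), float(I), int(obs[gi]), float(mean[gi]),
                         float(sd[gi]), float(z[gi])))
    df = pd.DataFrame(
        rows, columns=["k", "intensity", "n_communities", "null_mean", "null_sd", "z"]
    )
    df = df.sort_values(
        by=["z", "n_communities", "k", "intensity"],
        ascending=[False, False, True, False],
    ).reset_index(drop=True)
    return df
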