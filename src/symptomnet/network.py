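"""Partial-correlation networks: container, CSV round trip, GraphML export.

A :class:`SymptomNetwork` stores a symmetric, zero-diagonal matrix of
partial correlations over a fixed item set. Edge weights are the partial
correlations themselves; sparsity is a property of the values, not of the
storage (matrices stay dense).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .items import ItemMetadata, validate_items

_SYM_TOL = 1e-8


@dataclass
class SymptomNetwork:
    """Weighted signed network over questionnaire items."""

    items: list[ItemMetadata]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        validate_items(self.items)
        w = np.asarray(self.weights, dtype=float)
        p = len(self.items)
        if w.shape != (p, p):
            raise ValueError(f"weights must be {p}x{p}, got {w.shape}")
        asym = np.abs(w - w.T).max() if p else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"weights matrix asymmetric (max |w - w'| = {asym:.3g})")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        off = np.abs(w[~np.eye(p, dtype=bool)]) if p > 1 else np.array([0.0])
        if off.size and off.max() >= 1.0:
            raise ValueError("partial correlations must satisfy |w| < 1")
        self.weights = w

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def index_of(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item_id {item_id!r}") from None

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index_of(a), self.index_of(b)])

    def edge_list(self, tol: float = 0.0) -> list[tuple[str, str, float]]:
        """Unordered node pairs with |weight| > tol, in canonical item order."""
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(self.weights[i, j]) > tol:
                    out.append((self.item_ids[i], self.item_ids[j], float(self.weights[i, j])))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.item_ids, columns=self.item_ids)

    def to_networkx(self, tol: float = 0.0) -> nx.Graph:
        g = nx.Graph()
        for it in self.items:
            g.add_node(it.item_id, construct=it.construct.value)
        for a, b, w in self.edge_list(tol):
            g.add_edge(a, b, weight=w)
        return g


def edge_count(net: SymptomNetwork, tol: float = 0.0) -> int:
    """Number of unordered pairs with |weight| strictly above ``tol``."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    iu = np.triu_indices(net.p, 1)
    return int((np.abs(net.weights[iu]) > tol).sum())


def write_weights_matrix(net: SymptomNetwork, path: str | Path, digits: int | None = None) -> None:
    """Write the full symmetric matrix as CSV with item_id header row/column."""
    df = net.to_dataframe()
    fmt = f"%.{digits}f" if digits is not None else None
    df.to_csv(path, float_format=fmt)


def read_weights_matrix(
    path: str | Path, items: Sequence[ItemMetadata] | None = None
) -> SymptomNetwork:
    """Read a weights matrix CSV (full symmetric or lower-triangular grid).

    The file must carry item_ids as header row and first column. A
    lower-triangular grid (upper triangle blank, or all-zero while the lower
    triangle is not) is mirrored; a genuinely asymmetric full matrix is
    rejected. The diagonal is forced to zero.

    If ``items`` is given, the file's labels must match their ids exactly
    (any order); the returned network follows the order of ``items``.
    """
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError(f"{path}: header row and header column disagree")
    w = df.to_numpy(dtype=float)
    p = w.shape[0]
    upper = np.triu(np.nan_to_num(w, nan=0.0), 1)
    lower = np.tril(np.nan_to_num(w, nan=0.0), -1)
    upper_blank = np.isnan(w[np.triu_indices(p, 1)]).all() if p > 1 else True
    if upper_blank or (not upper.any() and lower.any()):
        w = lower + lower.T
    else:
        if np.isnan(w).any():
            raise ValueError(f"{path}: scattered missing entries in weights matrix")
        asym = np.abs(w - w.T).max()
        if asym > _SYM_TOL:
            raise ValueError(
                f"{path}: full matrix asymmetric beyond tolerance (max dev {asym:.3g})"
            )
    if items is None:
        # minimal metadata: unknown construct info is not required to hold a
        # weights matrix, so default to a generic 0-3 ordinal item set
        from .items import Construct

        meta = [ItemMetadata(lbl, Construct.DEPRESSION, 0, 3) for lbl in labels]
        order = list(range(p))
    else:
        meta = list(items)
        ids = [it.item_id for it in meta]
        unknown = set(labels) - set(ids)
        if unknown:
            raise ValueError(f"{path}: unknown item_ids {sorted(unknown)}")
        if set(ids) - set(labels):
            raise ValueError(f"{path}: file lacks items {sorted(set(ids) - set(labels))}")
        order = [labels.index(i) for i in ids]
    w = w[np.ix_(order, order)]
    return SymptomNetwork(items=meta, weights=w)


def write_graphml(net: SymptomNetwork, path: str | Path, tol: float = 0.0) -> None:
    nx.write_graphml(net.to_networkx(tol), path)
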