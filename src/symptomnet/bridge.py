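"""Bridge expected influence across a-priori construct clusters.

Bridge expected influence (1-step) of a node is the signed sum of its edge
weights to nodes of *other* constructs; together with the within-construct
sum it decomposes ordinary one-step expected influence exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .centrality import standardize
from .network import SymptomNetwork


def bridge_expected_influence(
    net: SymptomNetwork, clusters: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-node bridge EI table (raw, standardized, rank).

    ``clusters`` maps item_id -> cluster label; defaults to the items'
    construct metadata. Every node must be assigned to exactly one cluster.
    Rank 1 is the largest raw bridge EI.
    """
    if clusters is None:
        clusters = {it.item_id: it.construct.value for it in net.items}
    missing = [i for i in net.item_ids if i not in clusters]
    if missing:
        raise ValueError(f"nodes without cluster assignment: {missing}")
    labels = np.array([clusters[i] for i in net.item_ids])
    cross = labels[:, None] != labels[None, :]
    raw = (net.weights * cross).sum(axis=1)
    # constant bridge EI (e.g. no cross-cluster edges at all) has no z-scale
    z = standardize(raw) if len(raw) > 1 and raw.std(ddof=1) > 0 else np.zeros_like(raw)
    df = pd.DataFrame(
        {
            "construct": labels,
            "bridge_ei_raw": raw,
            "bridge_ei_z": z,
        },
        index=net.item_ids,
    )
    df["rank"] = df["bridge_ei_raw"].rank(ascending=False, method="min").astype(int)
    return df


def within_cluster_ei(
    net: SymptomNetwork, clusters: dict[str, str] | None = None
) -> np.ndarray:
    """Signed sum of each node's weights to its own cluster."""
    if clusters is None:
        clusters = {it.item_id: it.construct.value for it in net.items}
    labels = np.array([clusters[i] for i in net.item_ids])
    same = labels[:, None] == labels[None, :]
    return (net.weights * same).sum(axis=1)
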