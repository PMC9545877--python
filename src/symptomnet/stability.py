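"""Bootstrap stability analyses for estimated networks.

Two procedures, both re-running the *entire* estimation pipeline
(correlations, glasso path, BIC refits, stepwise search) per replicate:

- nonparametric bootstrap of edge weights: row resampling with
  replacement, per-edge percentile confidence intervals, and pairwise
  edge-difference tests (a difference is "significant" when the bootstrap
  95% CI of the difference excludes zero);
- case-dropping subset bootstrap for centrality stability: re-estimate on
  progressively smaller subsamples and correlate the re-estimated
  centralities with the full-sample ones. The CS coefficient is the
  largest drop proportion at which at least 95% of subsamples correlate at
  least 0.7 with the original index.

Replicates whose estimation fails are dropped and counted; more than 10%
failures aborts. A replicate whose centrality vector is constant (Pearson
correlation undefined) counts as a failed correlation (0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bridge import bridge_expected_influence
from .centrality import INDICES
from .data import ItemResponseTable
from .ggm import estimate_network
from .network import SymptomNetwork
from .simulate import child_rng

_STREAM_EDGE_BOOT = 3
_STREAM_CASE_DROP = 4

#: CS-coefficient convention: correlation threshold, required probability,
#: and the largest drop proportion considered. Configurable per call.
CS_CORRELATION = 0.7
CS_PROBABILITY = 0.95
CS_MAX_DROP = 0.75

DEFAULT_DROP_GRID = np.round(np.arange(0.05, 0.751, 0.05), 2)


def _index_fn(index: str) -> Callable[[SymptomNetwork], np.ndarray]:
    if index in INDICES:
        return INDICES[index]
    if index == "bridge_expected_influence":
        return lambda net: bridge_expected_influence(net)["bridge_ei_raw"].to_numpy()
    raise ValueError(f"unknown centrality index {index!r}")


@dataclass
class EdgeBootstrapReport:
    point_network: SymptomNetwork
    edge_index: list[tuple[str, str]]          # upper-triangle pair labels
    samples: np.ndarray = field(repr=False)    # B_ok x n_pairs edge weights
    edge_ci: pd.DataFrame = field(repr=False)  # point, ci_low, ci_high
    n_failed: int = 0

    def difference_test(self, alpha: float = 0.05, nonzero_only: bool = True) -> pd.DataFrame:
        """Pairwise edge-difference tests among (by default) nonzero edges.

        Entry (e1, e2) is True when the bootstrap CI of w_e1 - w_e2
        excludes zero.
        """
        w = self.point_network.weights
        iu = np.triu_indices(w.shape[0], 1)
        keep = np.flatnonzero(np.abs(w[iu]) > 0) if nonzero_only else np.arange(len(self.edge_index))
        labels = ["--".join(self.edge_index[i]) for i in keep]
        sub = self.samples[:, keep]
        lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
        out = np.zeros((len(keep), len(keep)), dtype=bool)
        for a in range(len(keep)):
            diff = sub[:, a][:, None] - sub[:, a + 1:]
            lo = np.percentile(diff, lo_q, axis=0)
            hi = np.percentile(diff, hi_q, axis=0)
            sig = (lo > 0) | (hi < 0)
            out[a, a + 1:] = sig
            out[a + 1:, a] = sig
        return pd.DataFrame(out, index=labels, columns=labels)


def bootstrap_edges(
    data: ItemResponseTable,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_failure_rate: float = 0.10,
    **estimator_kwargs,
) -> EdgeBootstrapReport:
    """Row-resampling bootstrap of the estimated edge weights."""
    if B < 50:
        raise ValueError("B must be >= 50")
    point = estimate_network(data, **estimator_kwargs)
    iu = np.triu_indices(data.p, 1)
    edge_index = [
        (data.item_ids[i], data.item_ids[j]) for i, j in zip(*iu)
    ]
    rng = child_rng(seed, _STREAM_EDGE_BOOT)
    draws = []
    failed = 0
    for _ in range(B):
        rows = rng.integers(0, data.n, size=data.n)
        sample = ItemResponseTable(items=data.items, responses=data.responses[rows])
        try:
            net = estimate_network(sample, **estimator_kwargs)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            failed += 1
            continue
        draws.append(net.weights[iu])
    if failed > max_failure_rate * B:
        raise RuntimeError(f"{failed}/{B} bootstrap replicates failed")
    samples = np.asarray(draws)
    lo = np.percentile(samples, 100 * alpha / 2, axis=0)
    hi = np.percentile(samples, 100 * (1 - alpha / 2), axis=0)
    edge_ci = pd.DataFrame(
        {
            "point": point.weights[iu],
            "ci_low": lo,
            "ci_high": hi,
        },
        index=["--".join(e) for e in edge_index],
    )
    return EdgeBootstrapReport(
        point_network=point,
        edge_index=edge_index,
        samples=samples,
        edge_ci=edge_ci,
        n_failed=failed,
    )


@dataclass
class CaseDropResult:
    index: str
    drop_grid: np.ndarray
    correlations: dict[float, np.ndarray] = field(repr=False)  # per level, draws
    cs_curve: pd.DataFrame = field(repr=False)
    cs_coefficient: float = 0.0

    def recompute_cs(
        self, threshold: float = CS_CORRELATION, probability: float = CS_PROBABILITY
    ) -> float:
        """CS coefficient from the stored correlation draws."""
        cs = 0.0
        for level in sorted(self.correlations):
            draws = self.correlations[level]
            if draws.size and np.mean(draws >= threshold) >= probability:
                cs = max(cs, level)
        return cs


def case_dropping(
    data: ItemResponseTable,
    index: str = "expected_influence",
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
    cs_correlation: float = CS_CORRELATION,
    cs_probability: float = CS_PROBABILITY,
    correlation_method: str = "pearson",
    max_failure_rate: float = 0.10,
    **estimator_kwargs,
) -> CaseDropResult:
    """Case-dropping subset bootstrap for one centrality index."""
    grid = np.asarray(sorted(set(float(g) for g in drop_grid)))
    if grid.size == 0 or grid.min() <= 0 or grid.max() > CS_MAX_DROP:
        raise ValueError(f"drop proportions must lie in (0, {CS_MAX_DROP}]")
    fn = _index_fn(index)
    full = fn(estimate_network(data, **estimator_kwargs))
    rng = child_rng(seed, _STREAM_CASE_DROP)
    correlations: dict[float, np.ndarray] = {}
    failed = 0
    for level in grid:
        keep_n = int(round(data.n * (1.0 - level)))
        draws = []
        for _ in range(B):
            rows = rng.choice(data.n, size=keep_n, replace=False)
            sample = ItemResponseTable(items=data.items, responses=data.responses[rows])
            try:
                vals = fn(estimate_network(sample, **estimator_kwargs))
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                failed += 1
                continue
            if np.std(vals) == 0 or np.std(full) == 0:
                r = 0.0
            elif correlation_method == "spearman":
                from scipy.stats import spearmanr

                r = float(spearmanr(full, vals).statistic)
            else:
                r = float(np.corrcoef(full, vals)[0, 1])
            draws.append(0.0 if np.isnan(r) else r)
        correlations[float(level)] = np.asarray(draws)
    total = B * grid.size
    if failed > max_failure_rate * total:
        raise RuntimeError(f"{failed}/{total} case-drop replicates failed")
    curve = pd.DataFrame(
        {
            "drop": grid,
            "mean_correlation": [correlations[g].mean() if correlations[g].size else np.nan for g in grid],
            "prop_above_threshold": [
                np.mean(correlations[g] >= cs_correlation) if correlations[g].size else np.nan
                for g in grid
            ],
        }
    )
    result = CaseDropResult(
        index=index, drop_grid=grid, correlations=correlations,
        cs_curve=curve, cs_coefficient=0.0,
    )
    result.cs_coefficient = result.recompute_cs(cs_correlation, cs_probability)
    return result
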