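"""Pairwise correlation matrices for ordinal item data.

Pearson is the default input to network estimation; Spearman and two-step
maximum-likelihood polychoric correlations are available for the ordinal
3/4-category items. Polychoric matrices assembled pairwise need not be
positive semi-definite and are repaired (eigenvalue clipping, re-scaled to
unit diagonal) with a warning when that happens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import ItemResponseTable
from .simulate import bvn_cdf


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix plus provenance tag."""

    matrix: np.ndarray = field(repr=False)
    method: str = "pearson"
    psd_repaired: bool = False

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("correlation matrix must be square")
        if np.abs(M - M.T).max() > 1e-10:
            raise ValueError("correlation matrix must be symmetric")
        if np.abs(np.diag(M) - 1.0).max() > 1e-10:
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(M)[0] < -1e-8:
            raise ValueError("correlation matrix has eigenvalue below -1e-8")
        self.matrix = (M + M.T) / 2.0

    @property
    def p(self) -> int:
        return self.matrix.shape[0]


def nearest_psd_correlation(M: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    vals, vecs = np.linalg.eigh((M + M.T) / 2.0)
    vals = np.clip(vals, floor, None)
    R = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def _polychoric_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML polychoric correlation of two integer-coded vectors."""
    xv, xc = np.unique(x, return_inverse=True)
    yv, yc = np.unique(y, return_inverse=True)
    cx, cy = len(xv), len(yv)
    if cx < 2 or cy < 2:
        raise ValueError("constant column in polychoric correlation")
    table = np.bincount(xc * cy + yc, minlength=cx * cy).reshape(cx, cy).astype(float)
    n = table.sum()
    # step 1: thresholds from marginal cumulative proportions
    tx = stats.norm.ppf(np.cumsum(table.sum(axis=1))[:-1] / n)
    ty = stats.norm.ppf(np.cumsum(table.sum(axis=0))[:-1] / n)
    gx = np.concatenate(([-9.0], tx, [9.0]))
    gy = np.concatenate(([-9.0], ty, [9.0]))
    H, K = np.meshgrid(gx, gy, indexing="ij")

    def negll(rho: float) -> float:
        G = bvn_cdf(H, K, rho)
        P = G[1:, 1:] - G[:-1, 1:] - G[1:, :-1] + G[:-1, :-1]
        return -float((table * np.log(np.clip(P, 1e-12, None))).sum())

    res = optimize.minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def correlation(data: ItemResponseTable, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise correlation matrix of the response table.

    Raises on constant columns (no correlation is defined there; the
    estimation pipeline requires every item to vary).
    """
    X = data.responses
    if data.n < 3:
        raise ValueError("need at least 3 respondents")
    variances = X.var(axis=0)
    if np.any(variances == 0):
        bad = [data.item_ids[j] for j in np.flatnonzero(variances == 0)]
        raise ValueError(f"constant columns: {bad}")
    if method == "pearson":
        M = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        M, _ = stats.spearmanr(X)
        M = np.atleast_2d(M)
    elif method == "polychoric":
        p = data.p
        M = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                M[i, j] = M[j, i] = _polychoric_pair(X[:, i], X[:, j])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    repaired = False
    if np.linalg.eigvalsh(M)[0] < -1e-8:
        warnings.warn(
            f"{method} correlation matrix not PSD; applying nearest-PSD repair",
            stacklevel=2,
        )
        M = nearest_psd_correlation(M)
        repaired = True
    return CorrelationMatrix(matrix=M, method=method, psd_repaired=repaired)
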