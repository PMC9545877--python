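"""Numba kernels for the two inner solvers of GGM estimation.

``ipf_fit`` runs the node-wise (covariance-selection) solver for the
constrained Gaussian MLE in place; ``glasso_cd`` runs Friedman-style block
coordinate descent for one graphical-lasso penalty, warm-startable across a
penalty path. Both operate on the implied covariance W; precision-matrix
extraction happens in :mod:`symptomnet.ggm`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def ipf_fit(S, adj, W, tol, max_sweeps):
    """Node-wise covariance updates until W matches S on edges and diagonal.

    Mutates W. Returns (sweeps_used, final_max_change).
    """
    p = S.shape[0]
    for j in range(p):
        W[j, j] = S[j, j]
    delta = np.inf
    sweeps = 0
    while sweeps < max_sweeps and delta >= tol:
        sweeps += 1
        delta = 0.0
        for j in range(p):
            m = 0
            for i in range(p):
                if adj[j, i]:
                    m += 1
            if m == 0:
                for i in range(p):
                    if i != j:
                        change = abs(W[i, j])
                        if change > delta:
                            delta = change
                        W[i, j] = 0.0
                        W[j, i] = 0.0
                continue
            N = np.empty(m, dtype=np.int64)
            c = 0
            for i in range(p):
                if adj[j, i]:
                    N[c] = i
                    c += 1
            A = np.empty((m, m))
            b = np.empty(m)
            for a in range(m):
                b[a] = S[N[a], j]
                for bb in range(m):
                    A[a, bb] = W[N[a], N[bb]]
            beta = np.linalg.solve(A, b)
            for i in range(p):
                if i == j:
                    continue
                v = 0.0
                for a in range(m):
                    v += W[i, N[a]] * beta[a]
                change = abs(W[i, j] - v)
                if change > delta:
                    delta = change
                W[i, j] = v
                W[j, i] = v
    return sweeps, delta


@njit(cache=False)
def glasso_cd(S, lam, W, B, tol, max_outer, inner_tol, max_inner):
    """Graphical lasso by block coordinate descent on the covariance W.

    W and B (per-node lasso coefficients, column j holds node j's beta over
    all rows, with B[j, j] unused) are mutated; pass the previous penalty's
    solution to warm-start a path. Only off-diagonal precision entries are
    penalized. Convergence: mean absolute change of the off-diagonal W
    entries below ``tol * mean |off-diagonal S|``.
    Returns the number of outer sweeps used.
    """
    p = S.shape[0]
    for j in range(p):
        W[j, j] = S[j, j]
    s_off = 0.0
    for i in range(p):
        for j in range(p):
            if i != j:
                s_off += abs(S[i, j])
    n_off = p * (p - 1)
    thresh = tol * (s_off / n_off if n_off > 0 else 1.0)
    outer = 0
    while outer < max_outer:
        outer += 1
        total_change = 0.0
        for j in range(p):
            # lasso subproblem for node j: 0.5 b'W11 b - s12'b + lam |b|_1
            for it in range(max_inner):
                max_step = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[l, j]
                    # soft threshold
                    if r > lam:
                        new = (r - lam) / W[k, k]
                    elif r < -lam:
                        new = (r + lam) / W[k, k]
                    else:
                        new = 0.0
                    step = abs(new - B[k, j])
                    if step > max_step:
                        max_step = step
                    B[k, j] = new
                if max_step < inner_tol:
                    break
            for i in range(p):
                if i == j:
                    continue
                v = 0.0
                for l in range(p):
                    if l != j:
                        v += W[i, l] * B[l, j]
                total_change += abs(v - W[i, j])
                W[i, j] = v
                W[j, i] = v
        if total_change / n_off < thresh:
            break
    return outer


@njit(cache=False)
def glasso_precision(S, lam, W, B):
    """Recover the precision matrix from a converged glasso solution."""
    p = S.shape[0]
    K = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for l in range(p):
            if l != j:
                dot += W[l, j] * B[l, j]
        kjj = 1.0 / (W[j, j] - dot)
        K[j, j] = kjj
        for l in range(p):
            if l != j:
                K[l, j] = -B[l, j] * kjj
    # symmetrize, preserving exact zeros of the lasso supports
    for i in range(p):
        for j in range(i + 1, p):
            if B[i, j] == 0.0 and B[j, i] == 0.0:
                K[i, j] = 0.0
                K[j, i] = 0.0
            else:
                v = 0.5 * (K[i, j] + K[j, i])
                K[i, j] = v
                K[j, i] = v
    return K
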