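"""Unregularized Gaussian graphical model estimation.

The estimator follows the glasso-path + BIC model-search recipe that is
standard in symptom-network psychometrics: generate candidate edge sets from
a graphical-lasso regularization path (100 penalties by default), refit each
candidate by constrained maximum likelihood *without* regularization, pick
the BIC-best refit, then greedily add/remove single edges until BIC stops
improving. Edge weights of the final model are the partial correlations
``rho_ij = -K_ij / sqrt(K_ii K_jj)`` of the fitted precision matrix K.

The constrained MLE (covariance selection) uses the classical node-wise
regression algorithm: iterate over nodes, solving for each node's
covariance column from its neighbours only, until the implied covariance
matches the sample covariance on every edge and on the diagonal. The
solver warm-starts from a previous fit, which makes the stepwise search and
bootstrap refits cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._fastops import glasso_cd, glasso_precision, ipf_fit
from .correlations import CorrelationMatrix, correlation
from .data import ItemResponseTable
from .network import SymptomNetwork

__all__ = [
    "GGMFit",
    "gaussian_loglik",
    "constrained_mle",
    "glasso_path",
    "stepwise_bic_search",
    "estimate_network",
    "bic",
]

EdgeSet = frozenset  # of (i, j) tuples with i < j


def _edges_to_adj(edge_set, p: int) -> np.ndarray:
    adj = np.zeros((p, p), dtype=bool)
    for i, j in edge_set:
        if not (0 <= i < p and 0 <= j < p and i != j):
            raise ValueError(f"invalid edge ({i}, {j}) for p = {p}")
        adj[i, j] = adj[j, i] = True
    return adj

def _adj_to_edges(adj: np.ndarray) -> EdgeSet:
    iu = np.triu_indices(adj.shape[0], 1)
    return frozenset(
        (int(i), int(j)) for i, j in zip(iu[0][adj[iu]], iu[1][adj[iu]])
    )


@dataclass
class GGMFit:
    """A fitted concentration-graph model."""

    edge_set: EdgeSet
    precision: np.ndarray = field(repr=False)
    log_likelihood: float = 0.0
    bic: float = 0.0
    n: int = 0
    implied_cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """Partial-correlation matrix derived from the precision matrix."""
        d = np.sqrt(np.diag(self.precision))
        W = -self.precision / np.outer(d, d)
        np.fill_diagonal(W, 0.0)
        return (W + W.T) / 2.0


def gaussian_loglik(S: np.ndarray | CorrelationMatrix, K: np.ndarray, n: int) -> float:
    """Profiled Gaussian log-likelihood (n/2)(log det K - tr(S K)).

    The additive constant -(n p / 2) log(2 pi) is dropped; it is identical
    for every model of the same data, so BIC differences are unaffected.
    """
    S = S.matrix if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    return 0.5 * n * (logdet - float(np.sum(S * K)))


def bic(log_likelihood: float, n_edges: int, n: int) -> float:
    """BIC with the edge count as the parameter count.

    Diagonal precision entries are free in every model of fixed p, so they
    cancel from BIC differences and are omitted.
    """
    return -2.0 * log_likelihood + n_edges * np.log(n)


def _fit_implied_cov(
    S: np.ndarray,
    adj: np.ndarray,
    tol: float,
    max_sweeps: int,
    W0: np.ndarray | None = None,
):
    """Node-wise solver for the implied covariance of the constrained MLE.

    Returns (W, n_sweeps, residual). At convergence W matches S on the
    diagonal and on every edge, and W^{-1} is zero off the edge set.
    """
    W = np.ascontiguousarray(S.copy() if W0 is None else W0.copy())
    sweeps, delta = ipf_fit(
        np.ascontiguousarray(S), np.ascontiguousarray(adj), W, tol, max_sweeps
    )
    residual = float(np.abs((W - S)[adj]).max(initial=0.0))
    return W, sweeps, max(float(delta), residual)


def _precision_from_w(S: np.ndarray, W: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Exact-zero precision matrix from the converged implied covariance."""
    p = S.shape[0]
    K = np.zeros((p, p))
    for j in range(p):
        N = np.flatnonzero(adj[j])
        if N.size == 0:
            K[j, j] = 1.0 / S[j, j]
        else:
            beta = np.linalg.solve(W[np.ix_(N, N)], S[N, j])
            kjj = 1.0 / (S[j, j] - S[N, j] @ beta)
            K[j, j] = kjj
            K[N, j] += -beta * kjj / 2.0
            K[j, N] += -beta * kjj / 2.0
    return (K + K.T) / 2.0


def constrained_mle(
    S: np.ndarray | CorrelationMatrix,
    edge_set,
    n: int = 0,
    tol: float = 1e-8,
    max_sweeps: int = 2000,
    warm_start: np.ndarray | None = None,
) -> GGMFit:
    """Gaussian MLE subject to K_ij = 0 for all pairs outside ``edge_set``.

    ``n`` only enters the stored log-likelihood/BIC (pass the sample size
    used to form S); the fitted matrices do not depend on it.
    """
    S = S.matrix if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    p = S.shape[0]
    adj = edge_set if isinstance(edge_set, np.ndarray) else _edges_to_adj(edge_set, p)
    n_edges = int(adj[np.triu_indices(p, 1)].sum())
    complete = n_edges == p * (p - 1) // 2
    if complete:
        W = S.copy()
    elif n_edges == 0:
        W = np.diag(np.diag(S)).astype(float)
    else:
        W, _, resid = _fit_implied_cov(S, adj, tol, max_sweeps, W0=warm_start)
        if resid > max(100 * tol, 1e-5):
            raise RuntimeError(
                f"constrained MLE did not converge (edge-covariance residual {resid:.3g})"
            )
    if complete:
        K = np.linalg.inv(S)
        K = (K + K.T) / 2.0
    else:
        K = _precision_from_w(S, W, adj)
    n_eff = n if n > 0 else 1
    ll = gaussian_loglik(S, K, n_eff)
    return GGMFit(
        edge_set=_adj_to_edges(adj),
        precision=K,
        log_likelihood=ll,
        bic=bic(ll, n_edges, n_eff),
        n=n_eff,
        implied_cov=W,
    )


def glasso_path(
    S: np.ndarray | CorrelationMatrix,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    zero_tol: float = 1e-8,
    tol: float = 1e-7,
) -> list[EdgeSet]:
    """Distinct edge sets along a graphical-lasso regularization path.

    Penalties are log-spaced between lambda_max (the smallest penalty
    giving the empty graph, i.e. max |off-diagonal S|) and
    lambda_max * lambda_min_ratio, largest first. The solver is block
    coordinate descent warm-started along the path; ``tol`` bounds the mean
    absolute off-diagonal change of the working covariance (relative to the
    mean |off-diagonal S|), a cheap surrogate for the duality gap.
    """
    S = S.matrix if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    p = S.shape[0]
    off = np.abs(S[~np.eye(p, dtype=bool)])
    lam_max = float(off.max(initial=0.0))
    if lam_max == 0.0:
        return [frozenset()]
    lams = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    edge_sets: list[EdgeSet] = []
    seen = set()
    S = np.ascontiguousarray(S)
    W = S.copy()
    B = np.zeros((p, p))
    for lam in lams:
        iters = glasso_cd(S, float(lam), W, B, tol, 500, 0.01 * tol * lam_max, 200)
        if iters >= 500:
            raise RuntimeError(f"graphical lasso did not converge at lambda={lam:.4g}")
        K = glasso_precision(S, float(lam), W, B)
        adj = np.abs(K) > zero_tol
        np.fill_diagonal(adj, False)
        es = _adj_to_edges(adj)
        if es not in seen:
            seen.add(es)
            edge_sets.append(es)
    return edge_sets


def _local_add_gain(S, W, n):
    """Vectorized lower bound on the log-likelihood gain of adding each edge.

    One exact IPF step on the pair clique {i, j}: the gain is
    (n/2)[log det W_C - log det S_C - 2 + tr(S_C W_C^-1)] for C = {i, j}.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        dW = np.outer(np.diag(W), np.diag(W)) - W * W
        dS = np.outer(np.diag(S), np.diag(S)) - S * S
        trace = (np.outer(np.diag(S), np.diag(W)) + np.outer(np.diag(W), np.diag(S))
                 - 2.0 * S * W) / dW
        gain = 0.5 * n * (np.log(dW) - np.log(dS) - 2.0 + trace)
    return gain


def stepwise_bic_search(
    S: np.ndarray | CorrelationMatrix,
    n: int,
    start,
    tol: float = 1e-8,
    search_tol: float = 1e-6,
    screen: int | None = None,
    max_moves: int | None = None,
    move_log: list | None = None,
) -> GGMFit:
    """Greedy single-edge BIC search from a starting edge set.

    Each candidate move (one edge added or removed) is scored by refitting
    the constrained MLE (warm-started from the current fit); the move with
    the largest BIC improvement is applied; the search stops at a local BIC
    optimum. Ties within 1e-10 prefer removals, then the lexicographically
    smallest pair. With ``screen=m`` only the m most promising additions and
    removals (ranked by an exact one-clique local likelihood bound) are
    refitted per step — an approximation used for bootstrap throughput.
    """
    S = S.matrix if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    p = S.shape[0]
    if max_moves is None:
        max_moves = 10 * p * (p - 1) // 2
    adj = start if isinstance(start, np.ndarray) else _edges_to_adj(start, p)
    adj = adj.copy()
    current = constrained_mle(S, adj, n=n, tol=tol)
    iu, ju = np.triu_indices(p, 1)
    for _ in range(max_moves):
        if screen is not None:
            gains = _local_add_gain(S, current.implied_cov
                                    if current.implied_cov is not None else
                                    np.linalg.inv(current.precision), n)
            K = current.precision
            d = np.sqrt(np.diag(K))
            pc2 = (K / np.outer(d, d)) ** 2
            candidates = []
            add_pairs = [(i, j) for i, j in zip(iu, ju) if not adj[i, j]]
            add_pairs.sort(key=lambda e: -gains[e[0], e[1]])
            candidates.extend(add_pairs[:screen])
            rem_pairs = [(i, j) for i, j in zip(iu, ju) if adj[i, j]]
            # least likelihood loss first: smallest current partial corr
            rem_pairs.sort(key=lambda e: pc2[e[0], e[1]])
            candidates.extend(rem_pairs[:screen])
        else:
            candidates = list(zip(iu, ju))
        best = None  # (bic, not is_removal, pair, fit)
        for i, j in candidates:
            i, j = int(i), int(j)
            is_removal = adj[i, j]
            adj[i, j] = adj[j, i] = not is_removal
            try:
                fit = constrained_mle(
                    S, adj, n=n, tol=search_tol, warm_start=current.implied_cov
                )
            except (RuntimeError, np.linalg.LinAlgError):
                adj[i, j] = adj[j, i] = is_removal
                continue
            adj[i, j] = adj[j, i] = is_removal
            key = (fit.bic, not is_removal, (i, j))
            if best is None or _move_better(key, best[0]):
                best = (key, fit, (i, j), is_removal)
        if best is None or best[0][0] >= current.bic - 1e-10:
            break
        (_, fit, (i, j), was_removal) = best
        adj[i, j] = adj[j, i] = not was_removal
        if move_log is not None:
            move_log.append(
                {"move": "remove" if was_removal else "add", "edge": (i, j),
                 "bic": float(fit.bic)}
            )
        current = fit
    else:
        raise RuntimeError("stepwise search exceeded its move budget")
    # final refit at full tolerance
    return constrained_mle(S, adj, n=n, tol=tol, warm_start=current.implied_cov)


def _move_better(key, best_key, tie_tol: float = 1e-10) -> bool:
    """Lower BIC wins; near-ties prefer removals, then smaller pairs."""
    if key[0] < best_key[0] - tie_tol:
        return True
    if key[0] > best_key[0] + tie_tol:
        return False
    return key[1:] < best_key[1:]


def fit_to_network(fit: GGMFit, items) -> SymptomNetwork:
    return SymptomNetwork(items=list(items), weights=fit.weights)


def estimate_network(
    data: ItemResponseTable,
    method: str = "pearson",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-8,
    stepwise: bool = True,
    screen: int | None = None,
    return_fit: bool = False,
    report: dict | None = None,
):
    """Full pipeline: correlations -> glasso path -> BIC refits -> stepwise.

    Returns the estimated :class:`SymptomNetwork` (and the underlying
    :class:`GGMFit` when ``return_fit`` is true). If a dict is passed as
    ``report`` it is filled with the path edge counts, the refit BIC
    trajectory, and the stepwise move log.
    """
    C = correlation(data, method=method)
    S, n = C.matrix, data.n
    path = glasso_path(S, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    best = None
    best_W = None
    bic_trajectory = []
    for es in path:
        fit = constrained_mle(S, es, n=n, tol=max(tol, 1e-7), warm_start=best_W)
        bic_trajectory.append((len(es), float(fit.bic)))
        if best is None or fit.bic < best.bic:
            best = fit
        best_W = fit.implied_cov
    move_log: list | None = [] if report is not None else None
    if stepwise:
        best = stepwise_bic_search(
            S, n, best.edge_set, tol=tol, screen=screen, move_log=move_log
        )
    if report is not None:
        report.update(
            correlation_method=C.method,
            psd_repaired=C.psd_repaired,
            n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio,
            path_edge_counts=[k for k, _ in bic_trajectory],
            path_bic=[b for _, b in bic_trajectory],
            stepwise_moves=move_log,
        )
    net = fit_to_network(best, data.items)
    return (net, best) if return_fit else net
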