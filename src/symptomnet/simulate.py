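"""Latent-Gaussian copula generator for ordinal questionnaire data.

The generative model: a p-dimensional standard multivariate normal latent
vector with a target correlation structure is discretized coordinate-wise by
strictly increasing thresholds into each item's integer score range. The
latent correlation matrix is specified indirectly through its partial
correlations (the natural parametrization for partial-correlation network
studies): the implied precision matrix has unit diagonal and off-diagonal
entries ``-rho_ij``; inverting and re-standardizing it yields the marginal
correlation matrix.

Calibration fits construct-shared, equally spaced thresholds to published
construct-level total-score means and SDs, and (optionally) rescales the
cross-construct latent correlation blocks so that the *observed* (post
discretization) total-score correlations match published targets. All
moments of the discretized variables are computed analytically from the
bivariate normal distribution, so calibration involves no simulation noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import owens_t
from scipy.stats import norm

from .data import ItemResponseTable
from .items import Construct, ItemMetadata, validate_items

__all__ = [
    "GeneratorSpec",
    "CalibrationTarget",
    "CalibrationResult",
    "CalibrationError",
    "partials_to_correlation",
    "correlation_to_partials",
    "generate_responses",
    "calibrate_thresholds",
    "bvn_cdf",
    "ordinal_moments",
]

# fixed spawn keys: one child random stream per operation, so adding an
# operation never perturbs the draws of existing ones
_STREAM_GENERATE = 0


def child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# bivariate normal machinery


def bvn_cdf(h, k, rho):
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal, vectorized.

    Uses Owen's T-function representation; accurate to ~1e-14 for
    |rho| <= 0.9999 (rho is clipped there, adequate for ordinal moments).
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    h = np.clip(h, -8.5, 8.5)
    k = np.clip(k, -8.5, 8.5)
    rho = np.clip(rho, -0.9999, 0.9999)
    # nudge exact zeros so the h==0 / k==0 branch of Owen's formula is taken
    # as a continuous limit
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (k / h - rho) / denom
    a_k = (h / k - rho) / denom
    beta = np.where(h * k < 0, 0.5, 0.0)
    out = 0.5 * (norm.cdf(h) + norm.cdf(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta
    return np.clip(out, 0.0, 1.0)


def _upper_orthant(h, k, rho):
    """P(Z1 > h, Z2 > k)."""
    return 1.0 - norm.cdf(h) - norm.cdf(k) + bvn_cdf(h, k, rho)


def ordinal_mean(thresholds: np.ndarray, min_score: int) -> float:
    """Mean of min_score + #{c : Z > t_c} for Z ~ N(0,1)."""
    return float(min_score + norm.sf(thresholds).sum())


def ordinal_cov(t1: np.ndarray, t2: np.ndarray, rho: float) -> float:
    """Covariance of two thresholded standard-normal coordinates.

    Uses the indicator decomposition X = min + sum_c 1[Z > t_c], so
    cov(X, Y) = sum_{c,d} [P(Z1 > t_c, Z2 > s_d) - sf(t_c) sf(s_d)].
    """
    H, K = np.meshgrid(t1, t2, indexing="ij")
    joint = _upper_orthant(H, K, rho)
    marg = np.outer(norm.sf(t1), norm.sf(t2))
    return float((joint - marg).sum())


def ordinal_var(thresholds: np.ndarray) -> float:
    t = np.asarray(thresholds, float)
    H, K = np.meshgrid(t, t, indexing="ij")
    joint = norm.sf(np.maximum(H, K))
    marg = np.outer(norm.sf(t), norm.sf(t))
    return float((joint - marg).sum())


def ordinal_moments(thresholds: np.ndarray, min_score: int) -> tuple[float, float]:
    """(mean, variance) of one discretized item."""
    return ordinal_mean(thresholds, min_score), ordinal_var(thresholds)


# ---------------------------------------------------------------------------
# partial <-> marginal correlation


def partials_to_correlation(latent_partials: np.ndarray) -> np.ndarray:
    """Marginal correlation matrix implied by a partial-correlation matrix.

    The implied precision matrix has unit diagonal and off-diagonal
    ``-rho_ij``; it must be positive definite.
    """
    P = np.asarray(latent_partials, float)
    p = P.shape[0]
    if P.shape != (p, p) or np.abs(P - P.T).max() > 1e-10:
        raise ValueError("latent_partials must be a symmetric square matrix")
    K = -P.copy()
    np.fill_diagonal(K, 1.0)
    eigvals = np.linalg.eigvalsh(K)
    if eigvals[0] <= 0:
        raise ValueError(
            f"implied precision matrix is not positive definite "
            f"(smallest eigenvalue {eigvals[0]:.6g})"
        )
    C = np.linalg.inv(K)
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def correlation_to_partials(R: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of a correlation matrix (zero diagonal)."""
    K = np.linalg.inv(np.asarray(R, float))
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return (P + P.T) / 2.0


# ---------------------------------------------------------------------------
# generator spec


@dataclass
class GeneratorSpec:
    """Full description of one synthetic ordinal dataset.

    thresholds maps item_id -> strictly increasing cut-points on the latent
    scale; an item with c categories needs c - 1 cut-points.
    """

    items: list[ItemMetadata]
    latent_partials: np.ndarray = field(repr=False)
    thresholds: dict[str, np.ndarray] = field(repr=False)
    n: int = 1041
    seed: int = 0

    def __post_init__(self) -> None:
        validate_items(self.items)
        p = len(self.items)
        self.latent_partials = np.asarray(self.latent_partials, float)
        if self.latent_partials.shape != (p, p):
            raise ValueError(f"latent_partials must be {p}x{p}")
        # raises if the implied precision matrix is not PD
        partials_to_correlation(self.latent_partials)
        for it in self.items:
            t = np.asarray(self.thresholds[it.item_id], float)
            if t.shape != (it.n_categories - 1,):
                raise ValueError(
                    f"item {it.item_id!r}: expected {it.n_categories - 1} "
                    f"cut-points, got {t.shape}"
                )
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"item {it.item_id!r}: thresholds must be increasing")
            self.thresholds[it.item_id] = t

    @property
    def latent_correlation(self) -> np.ndarray:
        return partials_to_correlation(self.latent_partials)


def generate_responses(spec: GeneratorSpec) -> ItemResponseTable:
    """Draw n latent MVN vectors and discretize; deterministic given seed."""
    p = len(spec.items)
    if spec.n < p + 1:
        warnings.warn(
            f"n = {spec.n} < p + 1 = {p + 1}: downstream estimation is ill-posed",
            stacklevel=2,
        )
    R = spec.latent_correlation
    L = np.linalg.cholesky(R)
    rng = child_rng(spec.seed, _STREAM_GENERATE)
    Z = rng.standard_normal((spec.n, p)) @ L.T
    X = np.empty((spec.n, p), dtype=np.int64)
    for j, it in enumerate(spec.items):
        X[:, j] = it.min_score + np.searchsorted(spec.thresholds[it.item_id], Z[:, j])
    return ItemResponseTable(items=list(spec.items), responses=X)


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationTarget:
    """Construct-level total-score moments to reproduce."""

    means: pd.Series
    sds: pd.Series
    correlations: pd.DataFrame

    def __post_init__(self) -> None:
        C = self.correlations.to_numpy(float)
        if np.abs(C - C.T).max() > 1e-10 or np.abs(np.diag(C) - 1).max() > 1e-10:
            raise ValueError("target correlation matrix must be symmetric, unit diagonal")
        if np.linalg.eigvalsh(C)[0] < -1e-10:
            raise ValueError("target correlation matrix must be positive semi-definite")


class CalibrationError(RuntimeError):
    """Raised when the threshold search cannot reach the target moments."""


@dataclass
class CalibrationResult:
    spec: GeneratorSpec
    achieved_means: pd.Series
    achieved_sds: pd.Series
    achieved_correlations: pd.DataFrame
    scale_factors: dict[tuple[str, str], float]


def _equally_spaced(m: float, s: float, n_cut: int) -> np.ndarray:
    offsets = np.arange(n_cut, dtype=float) - (n_cut - 1) / 2.0
    return m + s * offsets


def _block_total_moments(
    thresholds: np.ndarray, min_score: int, R_block: np.ndarray
) -> tuple[float, float]:
    """Analytic mean and variance of a construct total under shared thresholds."""
    k = R_block.shape[0]
    mu, v = ordinal_moments(thresholds, min_score)
    total_var = k * v
    for i in range(k):
        for j in range(i + 1, k):
            total_var += 2.0 * ordinal_cov(thresholds, thresholds, R_block[i, j])
    return k * mu, total_var


def _fit_construct_thresholds(
    construct_items: list[ItemMetadata],
    R_block: np.ndarray,
    target_mean: float,
    target_sd: float,
    mean_rtol: float = 0.02,
    sd_rtol: float = 0.10,
) -> np.ndarray:
    """Solve (location, spacing) of equally spaced shared thresholds."""
    it0 = construct_items[0]
    n_cut = it0.n_categories - 1
    k = len(construct_items)

    def residuals(x):
        m, log_s = x
        t = _equally_spaced(m, np.exp(log_s), n_cut)
        mean, var = _block_total_moments(t, it0.min_score, R_block)
        return [mean - target_mean, np.sqrt(var) - target_sd]

    # initial location from the marginal mean alone (spacing 1)
    item_mean_target = target_mean / k - it0.min_score

    def marg(m):
        return norm.sf(_equally_spaced(m, 1.0, n_cut)).sum() - item_mean_target

    m0 = optimize.brentq(marg, -6.0, 6.0)
    sol = optimize.least_squares(residuals, x0=[m0, 0.0], xtol=1e-12, ftol=1e-12)
    resid = residuals(sol.x)
    if abs(resid[0]) > mean_rtol * abs(target_mean) or abs(resid[1]) > sd_rtol * abs(
        target_sd
    ):
        raise CalibrationError(
            f"threshold search for construct {it0.construct.value!r} did not reach "
            f"the target moments (residuals: mean {resid[0]:+.4f}, sd {resid[1]:+.4f})"
        )
    return _equally_spaced(sol.x[0], np.exp(sol.x[1]), n_cut)


def _observed_cross_corr(
    R: np.ndarray,
    idx_a: list[int],
    idx_b: list[int],
    thr_a: np.ndarray,
    thr_b: np.ndarray,
    var_a: float,
    var_b: float,
    alpha: float = 1.0,
) -> float:
    cov = 0.0
    for i in idx_a:
        for j in idx_b:
            cov += ordinal_cov(thr_a, thr_b, np.clip(alpha * R[i, j], -0.999, 0.999))
    return cov / np.sqrt(var_a * var_b)


def calibrate_thresholds(
    items: list[ItemMetadata],
    target: CalibrationTarget,
    latent_partials: np.ndarray,
    n: int = 1041,
    seed: int = 0,
    match_correlations: bool = True,
) -> CalibrationResult:
    """Fit generator thresholds (and optionally cross-construct structure).

    Thresholds are shared across items within a construct (only
    construct-level moments are published) and equally spaced, giving two
    free parameters per construct for the two targets (total mean, total
    SD). With ``match_correlations=True`` the three cross-construct latent
    correlation blocks are additionally rescaled by scalar factors so the
    analytic observed total-score correlations match the target matrix; the
    rescaled matrix is checked for positive definiteness.
    """
    validate_items(items)
    R = partials_to_correlation(latent_partials)
    constructs = [c for c in Construct if any(it.construct is c for it in items)]
    idx = {c: [i for i, it in enumerate(items) if it.construct is c] for c in constructs}

    thresholds: dict[str, np.ndarray] = {}
    block_thr: dict[Construct, np.ndarray] = {}
    block_var: dict[Construct, float] = {}
    for c in constructs:
        block_items = [items[i] for i in idx[c]]
        R_block = R[np.ix_(idx[c], idx[c])]
        t = _fit_construct_thresholds(
            block_items, R_block, float(target.means[c.value]), float(target.sds[c.value])
        )
        block_thr[c] = t
        _, block_var[c] = _block_total_moments(t, block_items[0].min_score, R_block)
        for it in block_items:
            thresholds[it.item_id] = t.copy()

    scale = {}
    R_star = R.copy()
    if match_correlations:
        for a_pos, ca in enumerate(constructs):
            for cb in constructs[a_pos + 1 :]:
                tgt = float(target.correlations.loc[ca.value, cb.value])

                def f(alpha, ca=ca, cb=cb, tgt=tgt):
                    return (
                        _observed_cross_corr(
                            R, idx[ca], idx[cb], block_thr[ca], block_thr[cb],
                            block_var[ca], block_var[cb], alpha,
                        )
                        - tgt
                    )

                lo, hi = 0.0, 1.0
                if f(hi) < 0:  # need amplification; cap to keep |r| < 1
                    hi = min(1.5, 0.995 / np.abs(R[np.ix_(idx[ca], idx[cb])]).max())
                    if f(hi) < 0:
                        warnings.warn(
                            f"cross-block {ca.value}-{cb.value}: target correlation "
                            f"{tgt:.3f} unreachable; using maximal scaling", stacklevel=2,
                        )
                        alpha = hi
                    else:
                        alpha = optimize.brentq(f, 1.0, hi, xtol=1e-6)
                else:
                    alpha = optimize.brentq(f, lo, hi, xtol=1e-6)
                scale[(ca.value, cb.value)] = float(alpha)
                block = np.ix_(idx[ca], idx[cb])
                R_star[block] = alpha * R[block]
                R_star[np.ix_(idx[cb], idx[ca])] = R_star[block].T

        eigvals = np.linalg.eigvalsh(R_star)
        if eigvals[0] < 1e-10:
            ridge = abs(eigvals[0]) + 1e-8
            warnings.warn(
                f"rescaled latent correlation not PD (min eig {eigvals[0]:.3g}); "
                f"applying ridge repair {ridge:.3g}", stacklevel=2,
            )
            R_star = (R_star + ridge * np.eye(len(items))) / (1.0 + ridge)

    spec = GeneratorSpec(
        items=list(items),
        latent_partials=correlation_to_partials(R_star),
        thresholds=thresholds,
        n=n,
        seed=seed,
    )

    # analytic achieved moments under the final structure
    ach_mean, ach_sd = {}, {}
    for c in constructs:
        block_items = [items[i] for i in idx[c]]
        m, v = _block_total_moments(
            block_thr[c], block_items[0].min_score, R_star[np.ix_(idx[c], idx[c])]
        )
        ach_mean[c.value], ach_sd[c.value] = m, np.sqrt(v)
    names = [c.value for c in constructs]
    C = pd.DataFrame(np.eye(len(constructs)), index=names, columns=names)
    for a_pos, ca in enumerate(constructs):
        for cb in constructs[a_pos + 1 :]:
            r = _observed_cross_corr(
                R_star, idx[ca], idx[cb], block_thr[ca], block_thr[cb],
                block_var[ca], block_var[cb], 1.0,
            )
            C.loc[ca.value, cb.value] = C.loc[cb.value, ca.value] = r
    return CalibrationResult(
        spec=spec,
        achieved_means=pd.Series(ach_mean),
        achieved_sds=pd.Series(ach_sd),
        achieved_correlations=C,
        scale_factors=scale,
    )
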