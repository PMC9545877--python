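# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `symptomnet`. Everything stated here is computed by the
package's tests or scripts; nothing is asserted beyond what they verify.

## Gaussian graphical model estimation

**Model.** Item responses are summarized by a correlation matrix S; a GGM
with edge set E is the multivariate-normal model whose precision matrix K
satisfies `K_ij = 0` for all pairs outside E. Edge weights are partial
correlations `rho_ij = -K_ij / sqrt(K_ii K_jj)`. The profiled log-likelihood
convention is `l(K) = (n/2)(log det K - tr(S K))`; the additive constant
`-(np/2) log 2*pi` is dropped because it is identical across models of the
same data, so BIC *differences* — the only quantities the search uses — are
unaffected. BIC counts only edges as parameters (`-2 l + |E| log n`):
diagonal precision entries are free in every model of fixed p and cancel
from differences.

**Correlation input.** Default is Pearson on the raw integer scores.
Spearman and two-step maximum-likelihood polychoric correlations are
options; polychoric is consistent for the latent correlation under the
ordinal-Gaussian model the generator implements and is what the
parameter-recovery validation uses. Pairwise-assembled polychoric matrices
can be indefinite; eigenvalues are clipped at 1e-8 and the matrix rescaled
to unit diagonal, with a warning.

**Constrained MLE (covariance selection).** The node-wise regression
algorithm iterates over nodes, solving for each node's covariance column
from its current neighbours until the implied covariance W matches S on
every edge and on the diagonal (tolerance 1e-8 on the maximum change /
edge residual; iteration cap 2000 sweeps). The precision matrix is then
extracted column-wise, giving *exact* zeros off the edge set. The solver
warm-starts from any positive-definite W with the correct diagonal, which
makes stepwise-search and bootstrap refits cheap.

**Glasso path.** Candidate edge sets come from the graphical lasso solved
at 100 penalties log-spaced between `lambda_max = max |S_ij| (i != j)` (the
smallest penalty giving the empty graph) and `lambda_max / 100`
(`lambda_min_ratio = 0.01`, configurable; no convention for the lower bound
is universal). The solver is block coordinate descent on the covariance
with lasso subproblems per node, penalizing off-diagonal precision entries
only, warm-started along the path. Convergence uses a cheap duality-gap
surrogate: mean absolute change of off-diagonal W entries below
`1e-7 x mean |S_offdiag|`. Tests verify exact support agreement and value
agreement (5e-4) with scikit-learn's implementation, and check the KKT
optimality conditions independently.

**Stepwise BIC search.** From the BIC-best unregularized refit of the path
candidates, the search repeatedly evaluates the BIC of every single-edge
addition and removal (each via a warm-started constrained MLE at a relaxed
tolerance of 1e-6, with the accepted model refit at 1e-8) and applies the
best improving change until none improves. Ties within 1e-10 prefer
removals, then the lexicographically smallest pair, making the search
deterministic. A move cap of `10 p(p-1)/2` guards against floating-point
cycling. A *screened* mode ranks candidate additions by an exact one-clique
local likelihood bound (the gain of a single IPF step on the pair) and
removals by current partial-correlation magnitude, then refits only the
top m of each. Screening is an approximation used by the bootstrap loops
for throughput; on test problems it reproduces the exhaustive search's
edge set exactly, and the exhaustive mode remains the default for one-off
estimation.

**Properties checked.** Saturated and empty models against closed forms; a
three-node chain against its analytic precision; refit likelihood
dominating the penalized solution on the same support; the fixed-point
property of re-fitting a model on its own edge set; permutation
equivariance of the full pipeline; greedy-search BIC within the top 5% of
all 2^6 models at p = 4 and recovery of the empty graph from independent
data at n = 20000.

## Synthetic ordinal data

**Generative model.** A latent-Gaussian copula: draw `z ~ N(0, R)` and set
`x_j = min_j + #{c : z_j > t_jc}` for strictly increasing thresholds
`t_j`. The latent correlation matrix R is specified through a
partial-correlation matrix: the implied precision has unit diagonal and
off-diagonal `-rho_ij`, and R is its standardized inverse. This is the
natural parametrization when the target of inference is itself a
partial-correlation network, and discretization is monotone by
construction. One root seed with fixed per-operation spawn keys drives all
randomness, so adding operations never perturbs existing draws.

**Calibration.** Published data give only construct-level moments, so
thresholds are shared within construct and equally spaced (two parameters
per construct: location and spacing — exactly the degrees of freedom the
two targets, total mean and SD, determine). All moments of the discretized
items are computed analytically from the bivariate normal distribution via
Owen's T-function (`cov(x, y) = sum_{c,d} [P(z1 > t_c, z2 > s_d) -
sf(t_c) sf(s_d)]`), so calibration is a deterministic root-finding problem
with no simulation noise; the solver must land within 2% of the target
mean and 10% of the target SD or it raises with its residuals. The marked
right-skew of the depression/anxiety totals (mean 5.79, SD 6.10 on a 0-27
scale) is produced purely by asymmetric cut-point placement; latents stay
Gaussian.

Total-score correlations between constructs are additionally matched by
rescaling the three cross-construct blocks of the latent correlation
matrix by scalar factors found by root-finding on the analytic observed
(post-discretization) correlation. For the packaged reference targets all
three factors are below one (0.89-0.94), and scaling cross blocks toward
zero preserves positive definiteness; an explicit eigenvalue check with a
minimal ridge repair guards the general case. Parameter-recovery runs use
the *unscaled* structure (`match_correlations=False`) so the generating
partial correlations equal the reference weights matrix exactly.

**What the generator does not emulate.** Real questionnaire data exhibit
per-item threshold differences, local dependence beyond the Gaussian
copula, response styles, and demographic heterogeneity. Passing tests show
the pipeline recovers networks generated by the stated copula model — not
that any particular empirical dataset satisfies that model.

## Centrality

Expected influence is the signed row sum of the weights matrix. Closeness
and betweenness use edge lengths `1/|w|`: centrality of information flow
should not reward weak connections, and sign is irrelevant to path
strength — consistent with choosing EI (not strength) as the signed index.
Betweenness uses Brandes accumulation with fractional credit for tied
geodesics; ties are detected with an absolute tolerance of 1e-9 on path
length (exhaustively verified against simple-path enumeration at p = 8 and
against networkx). Standardization is the z-score with the sample (n-1)
SD; this convention reproduces the reference study's printed standardized
EI values (2.17, 1.46) from the printed weights to within two-decimal
rounding, which the tests assert with tolerance 0.10. On a disconnected
network closeness is computed within components and a warning is emitted
(the reference network is connected; no harmonic fallback is silently
substituted).

## Clique percolation

k-cliques are enumerated from the nonzero-edge skeleton (k-subsets of
maximal cliques); intensity is the geometric mean of *absolute* edge
weights — the reference network's mixed-sign community (containing the
-0.18 edge) percolates only under a magnitude convention. Retained cliques
sharing k-1 nodes chain into communities; nodes may belong to several
communities or none. Lowering I only adds cliques, so communities grow or
merge monotonically (tested), and every community is internally connected.

**Rounding sensitivity.** With the two-decimal reference matrix the triads
{PHQ8, PHQ9, GAD5} (intensity 0.2164) and {PHQ3, PHQ4, PHQ5} (0.2147) fall
just below the published threshold I = 0.225, and the bridging triad
{PHQ9, GAD2, GAD3} (0.2161) sits *between* them. Consequently no threshold
reproduces the published five-community figure exactly from the printed
weights: within I in [0.2115, 0.2147] the solution is the five published
communities with the depression-led and anxiety communities merged through
that bridging triad, and with exactly the published unassigned set
{PHQ1, PHQ7, GAD4, GAD6}. The acceptance test asserts precisely this
merged solution and the two rounding-robust communities at I = 0.225.

**Parameter search.** For each (k, I) on the grid (k = 3..6, I from 0.40
down to 0.01 in steps of 0.005, 100 permutations by default) the observed
community count is compared with its distribution under a null that
permutes the nonzero weights over the fixed edge skeleton — testing how
the weights organize on the topology, not the topology itself. Candidates
are ranked by the z-score of the observed count (ties: larger count, then
smaller k, then larger I). The cited literature does not pin down the
test statistic, so the ranking is a documented implementation choice and
the full diagnostic grid is always returned for manual selection.

## Bootstrap stability

Both procedures re-run the entire estimation per replicate (the bootstrap
targets the network estimator, not merely the correlations). Edge CIs are
percentile intervals from B row-resamples; the difference test declares
two edges distinct when the bootstrap 95% CI of their weight difference
excludes zero, computed among edges nonzero in the point estimate. The CS
coefficient for a centrality index is the largest drop proportion (grid up
to 0.75) at which at least 95% of B subsamples correlate at least 0.7
(Pearson, on raw values; Spearman optional) with the full-sample index;
the 0.7 / 0.95 / 0.75 constants follow the established convention for this
coefficient and are configurable. Replicates with estimation failures are
dropped and counted; above 10% the procedure aborts. A subsample with a
constant centrality vector counts as correlation 0. With a fixed seed the
entire report is bit-reproducible, and the CS coefficient can be recomputed
exactly from the stored correlation draws.

**Problem sizes.** The stability analyses in the test suite and the
acceptance script use reduced designs chosen to keep full re-estimation
per replicate: the acceptance run uses 8 drop levels x 50 subsamples with
the screened stepwise search; the suite uses 5 levels x 12-20. The CS
grid coarsens accordingly (coefficients land on grid points), which is
adequate for the bound and rank-order claims being checked.

## Known limitations

- Polychoric estimation is two-step and pairwise; at p = 19 the inverse of
  the assembled matrix amplifies pairwise noise, so recovered partial
  correlations at n = 20000 carry errors up to ~0.05 on strong edges.
- The stepwise search is greedy: it guarantees single-edge local
  optimality, not the global BIC optimum.
- The permutation (k, I) criterion favours strongly non-random *counts* of
  communities; alternative statistics (size distributions, node coverage)
  may rank grids differently, which is why the full grid is emitted.
- The printed two-decimal reference matrix limits every fixture-based
  check to rounding precision; tolerances state this explicitly where it
  matters (standardized EI +/-0.10, the community merge band).
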