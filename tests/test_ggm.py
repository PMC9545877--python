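"""GGM estimation: likelihood, constrained MLE, glasso path, stepwise search."""

import numpy as np
import pytest

from symptomnet import (
    GeneratorSpec,
    constrained_mle,
    correlation,
    estimate_network,
    gaussian_loglik,
    generate_responses,
    glasso_path,
    stepwise_bic_search,
)
from symptomnet.ggm import bic as bic_fn
from symptomnet.items import Construct, ItemMetadata

from _oracles import exhaustive_bic_search


def _corr_from_sample(rng, p, n=300):
    X = rng.standard_normal((n, p))
    return np.corrcoef(X, rowvar=False)


class TestCorrelationInput:
    def test_perfect_concordance(self):
        items = [ItemMetadata(x, Construct.ANXIETY, 0, 3) for x in "abc"]
        from symptomnet import ItemResponseTable

        col = np.tile(np.array([0, 1, 2, 3]), 10)
        tab = ItemResponseTable(items=items, responses=np.column_stack([col, col, col[::-1]]))
        C = correlation(tab, "pearson")
        assert C.matrix[0, 1] == pytest.approx(1.0)

    def test_constant_column_rejected(self):
        from symptomnet import ItemResponseTable

        items = [ItemMetadata(x, Construct.ANXIETY, 0, 3) for x in "ab"]
        tab = ItemResponseTable(items=items, responses=np.column_stack(
            [np.zeros(10, dtype=int), np.arange(10) % 4]))
        with pytest.raises(ValueError, match="constant"):
            correlation(tab)

    def test_independent_columns_near_zero(self):
        items = [ItemMetadata(x, Construct.ANXIETY, 0, 3) for x in "ab"]
        from symptomnet import ItemResponseTable

        rng = np.random.default_rng(4)
        tab = ItemResponseTable(
            items=items, responses=rng.integers(0, 4, size=(10_000, 2))
        )
        C = correlation(tab)
        assert abs(C.matrix[0, 1]) < 0.03

    def test_polychoric_recovers_latent_correlation(self):
        """Median-split items from latent rho = 0.5: polychoric ~ 0.5."""
        items = [ItemMetadata(x, Construct.ANXIETY, 0, 1) for x in "ab"]
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        thr = {"a": np.array([0.0]), "b": np.array([0.0])}
        spec = GeneratorSpec(items=items, latent_partials=P, thresholds=thr,
                             n=40_000, seed=2)
        tab = generate_responses(spec)
        C = correlation(tab, "polychoric")
        assert C.matrix[0, 1] == pytest.approx(0.5, abs=0.05)
        # Pearson on the dichotomized items is attenuated well below 0.5
        assert correlation(tab, "pearson").matrix[0, 1] < 0.42


class TestGaussianLoglik:
    def test_identity_closed_form(self):
        assert gaussian_loglik(np.eye(3), np.eye(3), 10) == pytest.approx(-15.0)

    def test_saturated_closed_form_p2(self):
        S = np.array([[1.0, 0.6], [0.6, 1.0]])
        K = np.linalg.inv(S)
        n = 50
        expected = (n / 2) * (-np.log(np.linalg.det(S)) - 2)
        assert gaussian_loglik(S, K, n) == pytest.approx(expected)

    def test_saturated_dominates(self, rng):
        S = _corr_from_sample(rng, 4)
        sat = gaussian_loglik(S, np.linalg.inv(S), 100)
        for _ in range(10):
            K = np.eye(4) * rng.uniform(0.5, 2)
            assert gaussian_loglik(S, K, 100) <= sat + 1e-9

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            gaussian_loglik(np.eye(2), np.array([[1.0, 2.0], [2.0, 1.0]]), 10)


class TestConstrainedMLE:
    def test_saturated_equals_inverse(self, rng):
        S = _corr_from_sample(rng, 5)
        full = frozenset((i, j) for i in range(5) for j in range(i + 1, 5))
        fit = constrained_mle(S, full, n=300)
        assert np.allclose(fit.precision, np.linalg.inv(S), atol=1e-8)

    def test_empty_graph_identity_for_correlation(self, rng):
        S = _corr_from_sample(rng, 5)
        fit = constrained_mle(S, frozenset(), n=300)
        assert np.allclose(fit.precision, np.eye(5))
        assert np.allclose(fit.weights, 0.0)

    def test_chain_closed_form(self):
        K_true = np.array([[1.5, -0.6, 0.0], [-0.6, 1.8, -0.5], [0.0, -0.5, 1.2]])
        S = np.linalg.inv(K_true)
        fit = constrained_mle(S, frozenset({(0, 1), (1, 2)}), n=100)
        assert np.allclose(fit.precision, K_true, atol=1e-7)
        # exact zero (not merely small) outside the edge set
        assert fit.precision[0, 2] == 0.0

    def test_implied_cov_matches_s_on_edges(self, rng):
        S = _corr_from_sample(rng, 6)
        edges = frozenset({(0, 1), (1, 2), (2, 3), (0, 3), (4, 5)})
        fit = constrained_mle(S, edges, n=200, tol=1e-10)
        W = np.linalg.inv(fit.precision)
        for i, j in edges:
            assert W[i, j] == pytest.approx(S[i, j], abs=1e-8)
        assert np.allclose(np.diag(W), np.diag(S), atol=1e-8)

    def test_weights_fixed_point(self, rng):
        S = _corr_from_sample(rng, 6)
        edges = frozenset({(0, 1), (1, 2), (3, 4), (2, 5)})
        fit1 = constrained_mle(S, edges, n=200)
        fit2 = constrained_mle(S, fit1.edge_set, n=200)
        assert np.allclose(fit1.weights, fit2.weights, atol=1e-9)

    def test_bic_identity(self, rng):
        S = _corr_from_sample(rng, 5)
        edges = frozenset({(0, 1), (2, 3)})
        fit = constrained_mle(S, edges, n=321)
        assert fit.bic == pytest.approx(
            bic_fn(fit.log_likelihood, len(fit.edge_set), 321), abs=1e-9
        )


class TestGlassoPath:
    def test_extremes(self, rng):
        S = _corr_from_sample(rng, 5)
        path = glasso_path(S, n_lambda=30)
        assert path[0] == frozenset()  # lambda = lambda_max
        # smallest penalties give dense graphs
        assert len(path[-1]) >= len(path[0])

    def test_against_sklearn_oracle(self, rng):
        """Support and precision values match sklearn's graphical lasso."""
        from sklearn.covariance import graphical_lasso as sk_glasso

        from symptomnet._fastops import glasso_cd, glasso_precision

        for _ in range(5):
            p = int(rng.integers(4, 9))
            S = np.ascontiguousarray(_corr_from_sample(rng, p, n=80))
            lam = float(rng.uniform(0.05, 0.5))
            W, B = S.copy(), np.zeros((p, p))
            glasso_cd(S, lam, W, B, 1e-10, 5000, 1e-13, 1000)
            K = glasso_precision(S, lam, W, B)
            _, K_ref = sk_glasso(S, alpha=lam, max_iter=2000, tol=1e-10)
            # stopping rules differ slightly; supports must agree exactly
            assert np.abs(K - K_ref).max() < 5e-4
            assert np.array_equal(np.abs(K) > 1e-6, np.abs(K_ref) > 1e-6)

    def test_kkt_optimality(self, rng):
        """Independent optimality check: glasso KKT conditions hold."""
        from symptomnet._fastops import glasso_cd, glasso_precision

        p = 6
        S = np.ascontiguousarray(_corr_from_sample(rng, p, n=100))
        lam = 0.15
        W, B = S.copy(), np.zeros((p, p))
        glasso_cd(S, lam, W, B, 1e-10, 5000, 1e-13, 1000)
        K = glasso_precision(S, lam, W, B)
        Winv = np.linalg.inv(K)
        for i in range(p):
            for j in range(i + 1, p):
                grad = S[i, j] - Winv[i, j]
                if K[i, j] == 0.0:
                    assert abs(grad) <= lam + 1e-6
                else:
                    assert grad == pytest.approx(-lam * np.sign(K[i, j]), abs=1e-6)

    def test_refit_likelihood_dominates_penalized_fit(self, rng):
        from symptomnet import gaussian_loglik
        from symptomnet._fastops import glasso_cd, glasso_precision

        p = 6
        S = np.ascontiguousarray(_corr_from_sample(rng, p, n=100))
        W, B = S.copy(), np.zeros((p, p))
        glasso_cd(S, 0.2, W, B, 1e-10, 5000, 1e-13, 1000)
        K_pen = glasso_precision(S, 0.2, W, B)
        adj = np.abs(K_pen) > 1e-8
        np.fill_diagonal(adj, False)
        refit = constrained_mle(S, adj, n=100)
        assert refit.log_likelihood >= gaussian_loglik(S, K_pen, 100) - 1e-9


class TestStepwiseSearch:
    def test_local_optimality(self, rng):
        S = _corr_from_sample(rng, 5, n=120)
        path = glasso_path(S, n_lambda=30)
        start = min(
            (constrained_mle(S, es, n=120) for es in path), key=lambda f: f.bic
        )
        final = stepwise_bic_search(S, 120, start.edge_set)
        pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        for pair in pairs:
            edges = set(final.edge_set)
            edges.symmetric_difference_update({pair})
            neighbour = constrained_mle(S, frozenset(edges), n=120)
            assert final.bic <= neighbour.bic + 1e-9

    def test_empty_graph_recovered_from_independent_data(self):
        """BIC consistency: independent data at large n gives ~no edges."""
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(10):
            X = rng.standard_normal((20_000, 6))
            S = np.corrcoef(X, rowvar=False)
            path = glasso_path(S, n_lambda=30)
            start = min(
                (constrained_mle(S, es, n=20_000) for es in path), key=lambda f: f.bic
            )
            final = stepwise_bic_search(S, 20_000, start.edge_set)
            if len(final.edge_set) <= 1:
                hits += 1
        assert hits >= 9

    def test_near_exhaustive_optimum_p4(self, rng):
        """Greedy BIC lands in the top 5% of all 64 models at p = 4."""
        successes = 0
        for trial in range(20):
            X = rng.standard_normal((150, 4))
            X[:, 1] += 0.8 * X[:, 0]
            X[:, 2] += 0.5 * X[:, 1]
            S = np.corrcoef(X, rowvar=False)
            all_bics = exhaustive_bic_search(S, n=150)
            path = glasso_path(S, n_lambda=30)
            start = min(
                (constrained_mle(S, es, n=150) for es in path), key=lambda f: f.bic
            )
            final = stepwise_bic_search(S, 150, start.edge_set)
            sorted_bics = sorted(all_bics.values())
            cutoff = sorted_bics[max(0, int(np.ceil(0.05 * len(sorted_bics))) - 1)]
            if final.bic <= cutoff + 1e-9:
                successes += 1
        assert successes >= 19

    def test_screened_matches_full_search(self, rng):
        S = _corr_from_sample(rng, 7, n=250)
        path = glasso_path(S, n_lambda=30)
        start = min(
            (constrained_mle(S, es, n=250) for es in path), key=lambda f: f.bic
        )
        full = stepwise_bic_search(S, 250, start.edge_set)
        screened = stepwise_bic_search(S, 250, start.edge_set, screen=8)
        assert screened.edge_set == full.edge_set


class TestEstimateNetwork:
    def test_permutation_equivariance(self, calibrated):
        from symptomnet import ItemResponseTable

        spec = calibrated.spec
        spec.seed = 55
        spec.n = 400
        tab = generate_responses(spec)
        net = estimate_network(tab, screen=10)
        rng = np.random.default_rng(0)
        perm = rng.permutation(tab.p)
        tab2 = ItemResponseTable(
            items=[tab.items[j] for j in perm], responses=tab.responses[:, perm]
        )
        net2 = estimate_network(tab2, screen=10)
        assert np.allclose(net2.weights, net.weights[np.ix_(perm, perm)], atol=1e-7)

    def test_independent_columns_yield_sparse_network(self):
        from symptomnet import ItemResponseTable

        items = [ItemMetadata(f"x{i}", Construct.ANXIETY, 0, 3) for i in range(8)]
        rng = np.random.default_rng(7)
        tab = ItemResponseTable(
            items=items, responses=rng.integers(0, 4, size=(5000, 8))
        )
        net = estimate_network(tab)
        assert len(net.edge_list()) <= 2

    def test_replicate_edge_density_near_reference(self, replicate_table):
        net = estimate_network(replicate_table, screen=10)
        density = len(net.edge_list()) / 171
        assert 0.2041 <= density <= 0.4041  # 30.41% +/- 10 points
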