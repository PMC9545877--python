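"""Latent-Gaussian generator: partial/marginal conversion, discretization,
threshold calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symptomnet import (
    GeneratorSpec,
    compute_scale_scores,
    correlation_to_partials,
    generate_responses,
    partials_to_correlation,
)
from symptomnet.items import Construct, ItemMetadata
from symptomnet.simulate import bvn_cdf, calibrate_thresholds, ordinal_moments


class TestPartialsToCorrelation:
    def test_zero_partials_give_identity(self):
        assert np.allclose(partials_to_correlation(np.zeros((4, 4))), np.eye(4))

    def test_two_nodes_partial_equals_marginal(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        R = partials_to_correlation(P)
        assert R[0, 1] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("a,b", [(0.3, 0.4), (-0.5, 0.2), (0.6, 0.6)])
    def test_three_node_chain_against_direct_inversion(self, a, b):
        # oracle: build the implied precision explicitly and invert with numpy
        P = np.array([[0, a, 0], [a, 0, b], [0, b, 0]], dtype=float)
        K = np.eye(3) - P
        C = np.linalg.inv(K)
        d = np.sqrt(np.diag(C))
        expected = C[0, 2] / (d[0] * d[2])
        R = partials_to_correlation(P)
        assert R[0, 2] == pytest.approx(expected, abs=1e-12)

    def test_round_trip_with_correlation_to_partials(self, ref_net):
        R = partials_to_correlation(ref_net.weights)
        assert np.allclose(correlation_to_partials(R), ref_net.weights, atol=1e-10)

    def test_non_positive_definite_rejected(self):
        # implied precision I - 0.9 (off-diagonal) has eigenvalue 1 - 1.8 < 0
        P = np.full((3, 3), 0.9)
        np.fill_diagonal(P, 0.0)
        with pytest.raises(ValueError, match="eigenvalue"):
            partials_to_correlation(P)


def _two_items(rho=0.0):
    items = [
        ItemMetadata("a", Construct.DEPRESSION, 0, 3),
        ItemMetadata("b", Construct.DEPRESSION, 0, 3),
    ]
    P = np.array([[0.0, rho], [rho, 0.0]])
    thr = {"a": np.array([-0.5, 0.3, 1.1]), "b": np.array([-0.5, 0.3, 1.1])}
    return items, P, thr


class TestGenerateResponses:
    def test_same_seed_bit_identical(self):
        items, P, thr = _two_items(0.4)
        spec = GeneratorSpec(items=items, latent_partials=P, thresholds=thr, n=500, seed=9)
        a = generate_responses(spec).responses
        b = generate_responses(spec).responses
        assert np.array_equal(a, b)

    def test_extreme_thresholds_give_constant_column(self):
        items, P, thr = _two_items()
        thr["a"] = np.array([8.5, 8.6, 8.7])  # all latent mass below first cut
        spec = GeneratorSpec(items=items, latent_partials=P, thresholds=thr, n=200, seed=1)
        tab = generate_responses(spec)
        assert (tab.responses[:, 0] == 0).all()

    def test_independent_latents_give_near_zero_correlations(self):
        items, P, thr = _two_items(0.0)
        spec = GeneratorSpec(items=items, latent_partials=P, thresholds=thr, n=50_000, seed=3)
        tab = generate_responses(spec)
        r = np.corrcoef(tab.responses, rowvar=False)[0, 1]
        assert abs(r) < 0.02

    def test_discretization_monotone_in_latent(self):
        # raising a latent draw never lowers the ordinal response
        thr = np.array([-0.8, 0.1, 0.9])
        z = np.sort(np.random.default_rng(0).standard_normal(1000))
        resp = np.searchsorted(thr, z)
        assert (np.diff(resp) >= 0).all()

    def test_small_n_warns(self):
        items, P, thr = _two_items(0.1)
        spec = GeneratorSpec(items=items, latent_partials=P, thresholds=thr, n=2, seed=0)
        with pytest.warns(UserWarning, match="ill-posed"):
            generate_responses(spec)


class TestBvnCdf:
    @given(
        h=st.floats(-3, 3), k=st.floats(-3, 3), rho=st.floats(-0.95, 0.95),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_scipy(self, h, k, rho):
        from scipy.stats import multivariate_normal

        ref = multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k])
        assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=1e-10)


class TestCalibration:
    def test_achieved_moments_match_targets(self, calibrated, ref_target):
        for c in ("loneliness", "depression", "anxiety"):
            assert calibrated.achieved_means[c] == pytest.approx(
                ref_target.means[c], rel=0.02
            )
            assert calibrated.achieved_sds[c] == pytest.approx(
                ref_target.sds[c], rel=0.10
            )
        assert calibrated.achieved_correlations.loc[
            "depression", "anxiety"
        ] == pytest.approx(0.805, abs=0.01)

    def test_simulated_moments_large_n(self, calibrated):
        spec = GeneratorSpec(
            items=calibrated.spec.items,
            latent_partials=calibrated.spec.latent_partials,
            thresholds=calibrated.spec.thresholds,
            n=100_000,
            seed=77,
        )
        scores = compute_scale_scores(generate_responses(spec))
        assert 4.87 <= scores.means["loneliness"] <= 5.07
        assert 5.5 <= scores.sds["depression"] <= 6.7

    def test_self_consistency_round_trip(self, calibrated):
        """Calibrating to the moments of a calibrated sample recovers them."""
        from symptomnet import CalibrationTarget

        big = GeneratorSpec(
            items=calibrated.spec.items,
            latent_partials=calibrated.spec.latent_partials,
            thresholds=calibrated.spec.thresholds,
            n=200_000,
            seed=5,
        )
        scores = compute_scale_scores(generate_responses(big))
        target2 = CalibrationTarget(
            means=scores.means, sds=scores.sds, correlations=scores.correlations
        )
        redo = calibrate_thresholds(
            calibrated.spec.items, target2, calibrated.spec.latent_partials, seed=6
        )
        for c in ("loneliness", "depression", "anxiety"):
            assert redo.achieved_means[c] == pytest.approx(scores.means[c], rel=0.02)
            assert redo.achieved_sds[c] == pytest.approx(scores.sds[c], rel=0.10)

    def test_unreachable_moments_raise(self, ref_net, ref_target):
        import pandas as pd

        from symptomnet import CalibrationTarget
        from symptomnet.simulate import CalibrationError

        bad = CalibrationTarget(
            means=pd.Series(
                {"loneliness": 4.97, "depression": 5.79, "anxiety": 5.03}
            ),
            sds=pd.Series({"loneliness": 1.867, "depression": 25.0, "anxiety": 5.521}),
            correlations=ref_target.correlations,
        )
        with pytest.raises(CalibrationError):
            calibrate_thresholds(ref_net.items, bad, ref_net.weights)

    def test_ordinal_moments_against_simulation(self):
        thr = np.array([-0.3, 0.5, 1.4])
        mean, var = ordinal_moments(thr, 0)
        z = np.random.default_rng(8).standard_normal(400_000)
        x = np.searchsorted(thr, z)
        assert mean == pytest.approx(x.mean(), abs=0.01)
        assert var == pytest.approx(x.var(), abs=0.01)
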