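import numpy as np
import pytest

from symptomnet import (
    calibrate_thresholds,
    default_items,
    generate_responses,
    load_reference_network,
    reference_calibration_target,
)


@pytest.fixture(scope="session")
def ref_net():
    return load_reference_network()


@pytest.fixture(scope="session")
def ref_target():
    return reference_calibration_target()


@pytest.fixture(scope="session")
def calibrated(ref_net, ref_target):
    """Generator calibrated to the reference study (thresholds + structure)."""
    return calibrate_thresholds(
        ref_net.items, ref_target, ref_net.weights, n=1041, seed=0
    )


@pytest.fixture(scope="session")
def replicate_table(calibrated):
    """One synthetic study replicate (n = 1041)."""
    spec = calibrated.spec
    spec.seed = 101
    return generate_responses(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_weighted_network(rng, p, density=0.5, signed=True):
    """Small random symmetric zero-diagonal weights matrix for oracle tests."""
    from symptomnet import ItemMetadata, SymptomNetwork
    from symptomnet.items import Construct

    w = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.05, 0.9, size=len(iu[0])) * mask
    if signed:
        vals *= rng.choice([-1.0, 1.0], size=len(iu[0]))
    w[iu] = vals
    w = w + w.T
    items = [ItemMetadata(f"n{i}", Construct.DEPRESSION, 0, 3) for i in range(p)]
    return SymptomNetwork(items=items, weights=w)


@pytest.fixture()
def make_random_network(rng):
    return lambda p, density=0.5, signed=True: random_weighted_network(
        rng, p, density, signed
    )
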