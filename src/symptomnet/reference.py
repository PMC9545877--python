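"""Packaged reference data for the 19-node loneliness/depression/anxiety network.

``load_reference_network`` returns the published partial-correlation weights
matrix (two-decimal precision, as printed) estimated from a nationally
representative general-population sample (N = 1041) collected in the early
COVID-19 lockdown period. ``reference_calibration_target`` returns the
construct-level total-score moments and correlations reported for the same
sample, used to calibrate the synthetic-data generator.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .items import default_items
from .network import SymptomNetwork, read_weights_matrix

#: sample size of the reference study
REFERENCE_N = 1041


def _fixture_path(name: str):
    return resources.files("symptomnet.fixtures").joinpath(name)


def load_reference_network() -> SymptomNetwork:
    """The 19-node reference network (52 nonzero edges of 171 possible)."""
    with resources.as_file(_fixture_path("lad19_weights.csv")) as path:
        return read_weights_matrix(path, items=default_items())


def reference_calibration_target():
    """Construct-level total-score moments of the reference sample.

    Returns a :class:`symptomnet.simulate.CalibrationTarget` with the
    reported means (4.97, 5.79, 5.03), SDs (1.867, 6.096, 5.521) and
    total-score correlations (Ln-PHQ .560, Ln-GAD .530, PHQ-GAD .805).
    """
    from .simulate import CalibrationTarget

    corr = pd.DataFrame(
        np.array(
            [
                [1.000, 0.560, 0.530],
                [0.560, 1.000, 0.805],
                [0.530, 0.805, 1.000],
            ]
        ),
        index=["loneliness", "depression", "anxiety"],
        columns=["loneliness", "depression", "anxiety"],
    )
    means = pd.Series({"loneliness": 4.97, "depression": 5.79, "anxiety": 5.03})
    sds = pd.Series({"loneliness": 1.867, "depression": 6.096, "anxiety": 5.521})
    return CalibrationTarget(means=means, sds=sds, correlations=corr)
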