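"""Shared fixtures: worked-example matrices and coefficient tables.

The reference objects below are small printed tables from a published
worked example of this analysis style (a poor-outcome patient's transition
matrix over six active of eight states, the patient-to-therapist dyad matrix,
per-subject standardized regression coefficients, and DeltaCorr class
components).  They serve as numeric inputs for consistency checks of the
package's own operations; they are data, not code paths.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcmnet.markov import TransitionMatrix

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# Worked-example patient transition matrix: probabilities over states 1..8,
# rows 5 and 6 undefined (states pruned as outliers).  Printed to 3 decimals.
EXAMPLE_PATIENT_PROBS = {
    1: [0.237, 0.042, 0.203, 0.025, 0.0, 0.0, 0.195, 0.297],
    2: [0.025, 0.125, 0.325, 0.125, 0.0, 0.0, 0.325, 0.075],
    3: [0.159, 0.057, 0.248, 0.038, 0.0, 0.0, 0.217, 0.280],
    4: [0.121, 0.030, 0.212, 0.091, 0.0, 0.0, 0.121, 0.424],
    7: [0.139, 0.062, 0.206, 0.026, 0.0, 0.0, 0.289, 0.278],
    8: [0.129, 0.031, 0.133, 0.043, 0.0, 0.0, 0.246, 0.418],
}

# Same dyad's patient-to-therapist matrix (simultaneous pairs).
EXAMPLE_P2T_PROBS = {
    1: [0.066, 0.246, 0.016, 0.131, 0.0, 0.0, 0.361, 0.180],
    2: [0.103, 0.069, 0.138, 0.052, 0.0, 0.0, 0.284, 0.353],
    3: [0.014, 0.264, 0.000, 0.125, 0.0, 0.0, 0.389, 0.208],
    4: [0.133, 0.084, 0.120, 0.120, 0.0, 0.0, 0.229, 0.313],
    7: [0.084, 0.113, 0.122, 0.084, 0.0, 0.0, 0.303, 0.294],
    8: [0.061, 0.187, 0.075, 0.140, 0.0, 0.0, 0.299, 0.238],
}

# Worked-example per-subject full-model standardized coefficients
# (beta_distance, beta_composite) for eight patients and their therapists.
EXAMPLE_PATIENT_BETAS = [
    (-0.295, 0.709),
    (-0.373, 0.697),
    (-0.405, 0.663),
    (-0.149, 0.806),
    (-0.369, 0.673),
    (-0.476, 0.645),
    (-0.452, 0.676),
    (-0.220, 0.763),
]
EXAMPLE_THERAPIST_BETAS = [
    (0.271, 1.006),
    (-0.036, 0.827),
    (0.057, 0.915),
    (-0.025, 0.784),
    (-0.069, 0.892),
    (-0.056, 0.750),
    (0.109, 0.875),
    (0.031, 0.877),
]

# Worked-example DeltaCorr class components: per-class mean Pearson r of the
# patient-side and therapist-side matrix correlations (n = 6 pairs each).
EXAMPLE_DELTACORR_COMPONENTS = {
    "poor-poor": {"corr_pat_mean": 0.830, "corr_ther_mean": 0.725, "n": 6},
    "good-good": {"corr_pat_mean": 0.796, "corr_ther_mean": 0.845, "n": 6},
}


def matrix_from_probs(prob_rows: dict[int, list[float]], k: int = 8, scale: int = 1000) -> TransitionMatrix:
    """Build a TransitionMatrix whose probabilities match printed 3-decimal rows."""
    counts = np.zeros((k, k), dtype=int)
    for row, probs in prob_rows.items():
        counts[row - 1] = np.round(np.asarray(probs) * scale).astype(int)
    return TransitionMatrix(k=k, counts=counts)


@pytest.fixture
def example_patient_mtm() -> TransitionMatrix:
    return matrix_from_probs(EXAMPLE_PATIENT_PROBS)


@pytest.fixture
def example_p2t_mtm() -> TransitionMatrix:
    return matrix_from_probs(EXAMPLE_P2T_PROBS)
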