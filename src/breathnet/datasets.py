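"""Bundled reference dataset: published per-participant network similarities.

A 12-participant normobaric-hypoxia cross-over study (control, ~2500 m
and ~3500 m simulated altitude; rest and isometric-exercise phases)
reported, for each participant, nine weighted-Jaccard similarities
between surrogate-thresholded TE networks, together with per-condition
symptom and headache counts.  Those printed values are bundled here so
the cohort statistics (repeated-measures ANOVAs, symptom chi-square,
McNemar) can be recomputed exactly from the published individual-level
data without access to the raw recordings.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_similarity_table", "symptom_counts",
           "REST_EXERCISE_COLUMNS", "REST_PHASE_COLUMNS",
           "EXERCISE_PHASE_COLUMNS"]

#: Column triples entering the three repeated-measures ANOVAs.
REST_EXERCISE_COLUMNS = ["rest_ex_CTR", "rest_ex_HY1", "rest_ex_HY2"]
REST_PHASE_COLUMNS = ["CTR_HY1_rest", "CTR_HY2_rest", "HY1_HY2_rest"]
EXERCISE_PHASE_COLUMNS = ["CTR_HY1_ex", "CTR_HY2_ex", "HY1_HY2_ex"]

_ROWS = [
    # sex, rest-ex (CTR, HY1, HY2), CTR-HY1 (rest, ex), CTR-HY2 (rest, ex),
    # HY1-HY2 (rest, ex)
    ("F", 0.388, 0.270, 0.330, 0.306, 0.135, 0.376, 0.327, 0.295, 0.144),
    ("F", 0.499, 0.510, 0.501, 0.589, 0.419, 0.586, 0.508, 0.512, 0.386),
    ("F", 0.535, 0.330, 0.377, 0.431, 0.513, 0.397, 0.466, 0.478, 0.469),
    ("F", 0.462, 0.125, 0.342, 0.187, 0.442, 0.357, 0.474, 0.134, 0.643),
    ("F", 0.326, 0.042, 0.445, 0.032, 0.482, 0.137, 0.459, 0.079, 0.379),
    ("F", 0.200, 0.098, 0.285, 0.256, 0.395, 0.288, 0.216, 0.328, 0.146),
    ("M", 0.268, 0.116, 0.262, 0.111, 0.035, 0.231, 0.270, 0.076, 0.024),
    ("M", 0.367, 0.165, 0.537, 0.200, 0.326, 0.392, 0.317, 0.223, 0.216),
    ("M", 0.533, 0.296, 0.317, 0.297, 0.422, 0.482, 0.382, 0.325, 0.358),
    ("M", 0.097, 0.280, 0.199, 0.250, 0.408, 0.286, 0.402, 0.204, 0.535),
    ("M", 0.369, 0.317, 0.307, 0.362, 0.461, 0.418, 0.478, 0.391, 0.315),
    ("M", 0.250, 0.274, 0.407, 0.330, 0.227, 0.337, 0.298, 0.427, 0.386),
]

_COLUMNS = ["sex", "rest_ex_CTR", "rest_ex_HY1", "rest_ex_HY2",
            "CTR_HY1_rest", "CTR_HY1_ex", "CTR_HY2_rest", "CTR_HY2_ex",
            "HY1_HY2_rest", "HY1_HY2_ex"]

#: Participants reporting symptoms / headache per condition (out of 12).
_SYMPTOMS = {"CTR": {"symptoms": 4, "headache": 2},
             "HY1": {"symptoms": 6, "headache": 3},
             "HY2": {"symptoms": 8, "headache": 2}}


def load_similarity_table() -> pd.DataFrame:
    """Per-participant WJSI values (12 rows, nine comparison columns)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def symptom_counts() -> tuple[dict, int]:
    """Per-condition symptom/headache counts and the sample size."""
    return ({c: dict(v) for c, v in _SYMPTOMS.items()}, 12)
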