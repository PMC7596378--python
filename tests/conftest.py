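"""Shared fixtures.

The 40-vs-40 mature/dysmature feature table is expensive (full feature
extraction per recording), so it is computed once per session and shared
between the direction-of-effect property tests and the acceptance suite.
Seeds are fixed; everything is generated programmatically.
"""

import numpy as np
import pandas as pd
import pytest

from neoqeeg.features import FeatureConfig, aggregate_channels, extract_features
from neoqeeg.simulate import DYSMATURE_PROFILE, MATURE_PROFILE, generate_eeg

DIRECTION_N = 40
DIRECTION_CHANNELS = ("C3", "C4")
DIRECTION_FS = 64.0
DIRECTION_DURATION = 120.0


@pytest.fixture(scope="session")
def direction_features():
    """Aggregated feature tables for 40 mature and 40 dysmature recordings.

    Seeds are paired: row i of each table was generated with the same
    seed index, so paired comparisons (sign tests) are valid.
    """
    cfg = FeatureConfig()
    tables = {}
    for key, profile, offset in (("mature", MATURE_PROFILE, 0),
                                 ("dysmature", DYSMATURE_PROFILE, 500_000)):
        rows = []
        for i in range(DIRECTION_N):
            rec = generate_eeg(profile, DIRECTION_DURATION, DIRECTION_FS,
                               DIRECTION_CHANNELS, seed=1000 + i + offset)
            rec.subject_id = f"{key}{i:02d}"
            rows.append(aggregate_channels(extract_features(rec, cfg)))
        tables[key] = pd.DataFrame(rows)
    return tables["mature"], tables["dysmature"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
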