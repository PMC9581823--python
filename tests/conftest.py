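import numpy as np
import pandas as pd
import pytest

import dfckit as dk


@pytest.fixture(scope="session")
def region_table():
    return dk.default_region_table()


@pytest.fixture
def small_regions():
    return dk.synthetic_region_table(6)


@pytest.fixture(scope="session")
def null_cohort():
    """Score-level cohort at study size with no group/time/slope structure."""
    return dk.simulate_cohort_scores(dk.SimulationConfig(seed=7)).cohort


@pytest.fixture(scope="session")
def reversal_cohort():
    """Cohort with opposite-sign dFC-cognition slopes across groups."""
    return dk.simulate_cohort_scores(dk.SimulationConfig.sign_reversal(0.8, seed=11)).cohort


@pytest.fixture
def tiny_cohort_frame():
    """Minimal hand-written manifest DataFrame (balanced 2/2/2)."""
    return pd.DataFrame(
        {
            "participant_id": [f"S{i}" for i in range(6)],
            "group": ["BCC_PLUS", "BCC_PLUS", "BCC_MINUS", "BCC_MINUS", "NC", "NC"],
            "age": [45.0, 52.0, 48.0, 55.0, 50.0, 47.0],
            "iq": [100.0, 110.0, 95.0, 105.0, 102.0, 108.0],
            "dmn_dfc_bl": [0.30, 0.28, 0.33, 0.25, 0.31, 0.27],
            "dmn_dfc_fu": [0.35, 0.30, 0.31, 0.28, 0.36, 0.24],
        }
    )


def pearson_oracle(x, y):
    """Two-pass textbook Pearson correlation (independent of numpy.corrcoef)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
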