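import numpy as np
import pandas as pd
import pytest

from scanharm.synthetic import SimConfig, simulate_cohort
from scanharm.tables import CohortTable


@pytest.fixture(scope="session")
def small_cohort():
    """6 scanners x 40 subjects, 8 ROIs, 5 IQMs — shared read-only fixture."""
    cfg = SimConfig(n_scanners=6, subjects_per_scanner=40, n_rois=8, n_iqms=5, seed=123)
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_table():
    """Hand-built 4-subject table over 2 scanners and 2 ROIs."""
    data = pd.DataFrame(
        {
            "subject_id": ["a", "b", "c", "d"],
            "scanner": ["s1", "s1", "s2", "s2"],
            "age": [20.0, 30.0, 40.0, 50.0],
            "sex": [0, 1, 0, 1],
            "tiv": [1.5e6, 1.5e6, 1.4e6, 1.6e6],
            "hippocampus": [3000.0, 3100.0, 2900.0, 3050.0],
            "amygdala": [1500.0, 1600.0, 1450.0, 1580.0],
        }
    )
    return CohortTable(data, roi_cols=("hippocampus", "amygdala"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
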