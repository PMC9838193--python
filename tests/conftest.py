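import numpy as np
import pandas as pd
import pytest

from recovery_valley.data_io import ExperimentSchedule, ObservedCounts
from recovery_valley.success import ActionPolicy, WellGeometry


@pytest.fixture(scope="session")
def geometry():
    return WellGeometry()


@pytest.fixture()
def tiny_schedule():
    """Three modelled days: a no-video test day, a rest day, a video test day."""
    return ExperimentSchedule(pd.DataFrame({
        "day": [5, 6, 7],
        "has_training": [True, False, True],
        "well_mm": [13.0, np.nan, 13.0],
        "n_training_trials": [20, 0, 20],
        "has_test": [True, False, True],
        "n_test_trials_per_well": [10, 0, 10],
    }))


@pytest.fixture()
def tiny_observations():
    test = pd.DataFrame({
        "day": [5] * 5,
        "well_mm": [13.0, 12.0, 11.0, 10.5, 10.0],
        "n": [10] * 5,
        "s": [3, 2, 2, 1, 0],
    })
    video = pd.DataFrame({
        "day": [7] * 4,
        "well_mm": [13.0, 13.0, 12.0, 12.0],
        "action": ["precision", "compensatory"] * 2,
        "n_selected": [4, 6, 2, 8],
        "s_success": [1, 3, 0, 2],
    })
    # remaining wells of day 7 observed without video classification is not
    # allowed (a video day classifies everything), so keep day 7 video-only
    return ObservedCounts(test, video)


@pytest.fixture()
def tiny_policy():
    return ActionPolicy(days=(5, 7), p_precision=(0.2, 0.6))
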