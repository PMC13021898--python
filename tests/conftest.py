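import numpy as np
import pandas as pd
import pytest

from rsk import design as dsg
from rsk import observer as obs
from rsk.study import build_study_log


@pytest.fixture(scope="session")
def exp3_plan():
    return dsg.build_exp3_design(seed=0)


@pytest.fixture(scope="session")
def exp3_log_small():
    """Pooled task-switching log of 12 synthetic participants (defaults)."""
    return build_study_log("3", 12, seed=0)


@pytest.fixture(scope="session")
def default_params():
    return obs.default_params()


def make_trial(**overrides) -> dict:
    """A minimal well-formed bivalent trial record for unit tests."""
    trial = {
        "participant_id": 0,
        "experiment": "3",
        "block_index": 0,
        "trial_index": 1,
        "task": dsg.MOTION,
        "motion_coherence": 0.75,
        "direction": "rightward",
        "color_coherence": 0.75,
        "majority_color": "khaki",
        "csi_ms": np.nan,
        "sequence_type": "single",
        "congruent": pd.NA,
        "congruency_n_minus_1": pd.NA,
        "correct_response": "right",
        "response": pd.NA,
        "rt_ms": np.nan,
        "correct": pd.NA,
    }
    trial.update(overrides)
    return trial
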