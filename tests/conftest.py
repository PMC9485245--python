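import numpy as np
import pytest

from spiralflow import behavior, tuning


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    """Fine 4-AFC design with few reps, for fast session-level tests."""
    return behavior.TaskDesign.fine(reps_per_level=5)


@pytest.fixture
def default_params():
    return behavior.DecisionModelParams()


def make_peaked_curve(plane, pref_deg, peak=30.0, floor=0.001, n_reps=5):
    """Tuning curve with all mass at one direction (deterministic trials)."""
    dirs = np.array([-135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0, 180.0])
    trials = [
        np.full(n_reps, peak if np.isclose(d, pref_deg) else floor) for d in dirs
    ]
    return tuning.TuningCurve.from_trials(plane, dirs, trials)


@pytest.fixture
def fovea_rf():
    return tuning.ReceptiveField((0.0, 0.0), 20.0, 20.0)
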