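import warnings

import pytest
from hypothesis import settings

from navscope.geometry import ymaze_geometry
from navscope.simulate import SimConfig, simulate_session

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geom():
    return ymaze_geometry()


@pytest.fixture(scope="session")
def default_session():
    """One default-condition synthetic session shared across tests.

    500 neurons (20 position / 20 path / 40 acceleration / 5+5 conjunctive /
    410 untuned), 600 s at 10 Hz on the neural clock.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        session, gt, kin, regions, trials = simulate_session(SimConfig(seed=3))
    return {"session": session, "ground_truth": gt, "kin": kin,
            "regions": regions, "trials": trials}


@pytest.fixture(scope="session")
def short_session():
    """A small 150-s session for cheap structural tests."""
    cfg = SimConfig(seed=7, session_duration=150.0, n_neurons=30,
                    class_counts={"position": 6, "path": 4, "acceleration": 6,
                                  "conjunctive_accel_position": 2,
                                  "conjunctive_accel_path": 2, "untuned": 10})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        session, gt, kin, regions, trials = simulate_session(cfg)
    return {"session": session, "ground_truth": gt, "kin": kin,
            "regions": regions, "trials": trials, "config": cfg}


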