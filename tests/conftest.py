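import numpy as np
import pytest

import ckc
from ckc.design import separate_design
from ckc.epoching import EpochSpec, make_epochs
from ckc.simulate import default_ground_truth, synth_session
from ckc.source import reduce_leadfield


@pytest.fixture(scope="session")
def array32():
    return ckc.default_sensor_array(32)


@pytest.fixture(scope="session")
def grid4():
    """125-node cubic grid, 4 mm spacing, hand-knob region."""
    return ckc.cubic_grid(half_extent_mm=8.0, spacing_mm=4.0)


@pytest.fixture(scope="session")
def leadfield32(grid4, array32):
    return reduce_leadfield(ckc.make_toy_leadfield(grid4, array32))


@pytest.fixture(scope="session")
def coupled_session(grid4, leadfield32):
    """A separate-condition D2 run with default coupling, plus its epochs."""
    design = separate_design("D2", n_bursts=2, burst_s=40.0)
    truth = default_ground_truth(grid4, seed=0)
    rec, kins, train = synth_session(design, truth, leadfield32)
    epochs = make_epochs(rec, kins["D2"], EpochSpec(), design.burst_schedule)
    return {"design": design, "truth": truth, "recording": rec,
            "kinematics": kins, "train": train, "epochs": epochs}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
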