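import numpy as np
import pytest

from epicortex import core, synth


@pytest.fixture(scope="session")
def sim_config():
    return synth.SimConfig(seed=1)


@pytest.fixture(scope="session")
def control_epoch():
    return core.segment_epochs([("control", 0.0, 360.0)], guard_s=30.0)


@pytest.fixture(scope="session")
def synthetic_recording(sim_config, control_epoch):
    """One 300-s control recording: 60 units of all classes, with truth."""
    templates, gt = synth.make_units(sim_config, np.random.default_rng(1))
    trains = synth.simulate_trains(gt, control_epoch, sim_config,
                                   np.random.default_rng(101),
                                   templates=templates)
    return trains, gt
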