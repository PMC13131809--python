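import numpy as np
import pytest

from ssdpriors.synth import GroundTruth, gen_behavior, gen_neuron


@pytest.fixture(scope="session")
def behavior_session():
    """Mid-sized behavioral session from the default ground-truth model."""
    return gen_behavior(GroundTruth(), n_trials=1500, seed=5)


@pytest.fixture(scope="session")
def anti_bayesian_neuron(behavior_session):
    truth = GroundTruth(pattern="anti_bayesian", modulation_depth=8.0)
    return gen_neuron(truth, behavior_session, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
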