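import numpy as np
import pytest

import blinkdeconv as bd
from blinkdeconv.synthetic import NoiseModel


@pytest.fixture(scope="session")
def quiet_config():
    """Small noiseless world without animal trials: every response is
    exactly representable by the FIR model."""
    return bd.SimulationConfig(
        n_blocks=6, seed=3, noise=NoiseModel(kind="none"),
        category_probs=(("face", 0.3), ("nonface", 0.7), ("animal", 0.0)))


@pytest.fixture(scope="session")
def quiet_truth():
    truth = bd.GroundTruth.from_rois(["V1"])
    return truth


@pytest.fixture(scope="session")
def quiet_session(quiet_config, quiet_truth):
    hfb, events = bd.synthetic.generate_hfb_session(quiet_config, quiet_truth)
    return hfb, events


@pytest.fixture(scope="session")
def noisy_session():
    cfg = bd.SimulationConfig(
        n_blocks=6, seed=7, noise=NoiseModel(sd=5.0),
        category_probs=(("face", 0.3), ("nonface", 0.7), ("animal", 0.0)))
    truth = bd.GroundTruth.from_rois(["V1"])
    hfb, events = bd.synthetic.generate_hfb_session(cfg, truth)
    return cfg, truth, hfb, events


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
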