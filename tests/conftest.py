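import numpy as np
import pytest

import ihcexo as ix


@pytest.fixture(scope="session")
def control_params():
    return ix.reference_params("control")


@pytest.fixture(scope="session")
def mutant_params():
    return ix.reference_params("mutant")


@pytest.fixture(scope="session")
def train_protocol():
    return ix.build_protocol("train")


@pytest.fixture(scope="session")
def train_drive(train_protocol):
    return ix.make_drive(train_protocol)


@pytest.fixture(scope="session")
def control_train_curve(control_params, train_protocol):
    """Noise-free cumulative dC_m curve of the control model over the train."""
    return ix.synth_cm_observation(
        control_params, train_protocol, noise_sd=0.0, seed=0, dt=0.1
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
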