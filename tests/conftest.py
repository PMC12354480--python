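import numpy as np
import pytest

from leafn.fvcb import FvCBParams
from leafn.synthetic import DesignConfig, TruthProfile, generate_experiment


@pytest.fixture(scope="session")
def default_params() -> FvCBParams:
    """Reference FvCB parameter set used across fitting tests."""
    return FvCBParams(vcmax=60.0, jmax=120.0, rd=1.0)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Zero-noise synthetic experiment: the pipeline must recover it exactly."""
    config = DesignConfig(seed=101)
    return generate_experiment(config, TruthProfile.default(config).zero_noise())


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise synthetic experiment (the study's design and noise levels)."""
    config = DesignConfig(seed=202)
    return generate_experiment(config, TruthProfile.default(config))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
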