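import numpy as np
import pytest

from printopt.fixtures import builtin_fixtures
from printopt.synthetic import GroundTruthModel, generate_study


@pytest.fixture(scope="session")
def bundle():
    return builtin_fixtures()


@pytest.fixture(scope="session")
def noiseless_truth():
    return GroundTruthModel(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_truth):
    return generate_study(11, truth=noiseless_truth, seed=11)


@pytest.fixture(scope="session")
def noisy_study():
    return generate_study(11, truth=GroundTruthModel(noise_sd=2.0, seed=4), seed=4)
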