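import numpy as np
import pytest

from npskin.datamodel import FeatureEncoder, depth_labels
from npskin.impute import mice_impute, pool_completed
from npskin.synth import GeneratorConfig, generate_frame


@pytest.fixture(scope="session")
def small_frame():
    """Literature-like dataset (n=200) with default missingness."""
    return generate_frame(GeneratorConfig(n_records=200, seed=7))


@pytest.fixture(scope="session")
def encoder(small_frame):
    return FeatureEncoder().fit(small_frame)


@pytest.fixture(scope="session")
def encoded(small_frame, encoder):
    return encoder.transform(small_frame)


@pytest.fixture(scope="session")
def complete_fm(encoded):
    return pool_completed(mice_impute(encoded, m=2, n_iterations=4, seed=3), "mean")


@pytest.fixture(scope="session")
def labels(small_frame):
    return depth_labels(small_frame)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
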