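import numpy as np
import pytest

from sdfasart import NetworkParams, SyntheticSpec, generate_synthetic, normalize


@pytest.fixture
def params() -> NetworkParams:
    return NetworkParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def study_dataset():
    """Synthetic dataset in the reference study shape (7 users x 15 = 105)."""
    return generate_synthetic(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def study_patterns(study_dataset):
    patterns, _ = normalize(study_dataset)
    return patterns


def random_category_triple(rng: np.random.Generator, n_features: int):
    """A valid (W, C, V) triple: three sorted draws per feature."""
    draws = np.sort(rng.uniform(0, 1, size=(3, n_features)), axis=0)
    return draws[0], draws[1], draws[2]
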