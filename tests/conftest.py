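import numpy as np
import pytest

from ctgaug.fixtures import FixtureConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_split():
    """A 200-record imbalanced split shared by the slower integration tests."""
    config = FixtureConfig(
        train_counts={"normal": 120, "suspicious": 15, "pathological": 10},
        test_counts={"normal": 45, "suspicious": 6, "pathological": 4},
        seed=42,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def small_matrices(small_split):
    from ctgaug.interface import prepare_model_matrices

    return prepare_model_matrices(small_split)
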