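import numpy as np
import pytest
from hypothesis import settings

from vitabind import (
    GeneratorConfig,
    build_feature_matrix,
    compute_binding_propensities,
    generate_dataset,
)


settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact planted-signal dataset shared by read-only tests."""
    cfg = GeneratorConfig(n_sequences=8, length_range=(20, 35), seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    ds = small_dataset
    prop = compute_binding_propensities(ds.records)
    return build_feature_matrix(ds.records, ds.profiles, ds.ss, prop)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
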