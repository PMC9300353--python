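import numpy as np
import pytest

from chaosfs import CGOParams, FeatureTable, GeneratorSpec, make_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_params():
    return CGOParams(dim=3, population_size=6, max_iterations=5, rng_seed=0)


@pytest.fixture
def separable_table():
    """Two classes split cleanly by feature 0; features 1-3 are noise."""
    rng = np.random.default_rng(42)
    n = 80
    labels = np.repeat([0, 1], n // 2)
    values = rng.standard_normal((n, 4))
    values[:, 0] = labels * 10.0 + rng.standard_normal(n) * 0.1
    split = np.array(["train", "test"] * (n // 2))
    return FeatureTable(values=values, labels=labels, split=split)


@pytest.fixture
def planted_spec():
    return GeneratorSpec.simple(
        n_per_class=60, n_classes=2, dim=16, n_informative=3,
        class_separation=1.5, rng_seed=11,
    )


@pytest.fixture
def planted_table(planted_spec):
    return make_feature_table(planted_spec)
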