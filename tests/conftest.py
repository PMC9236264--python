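import numpy as np
import pytest

from fatiguecast import CohortConfig, build_schema, generate_cohort
from fatiguecast.schema import FeatureSchema


@pytest.fixture(scope="session")
def clinical_schema():
    return build_schema("clinical")


@pytest.fixture(scope="session")
def small_schema():
    """A compact 12-feature schema (3 tags x 4 features) for fast tests."""
    names, tags = [], []
    for block in "abc":
        for i in range(4):
            names.append(f"{block}{i}")
            tags.append(block)
    return FeatureSchema("clinical", tuple(names), tuple(tags))


@pytest.fixture(scope="session")
def planted_cohort(small_schema):
    """54-subject cohort with 3 strongly planted features (effect 2)."""
    cfg = CohortConfig(schema=small_schema, planted_features=(1, 5, 9),
                       effect_size=2.0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
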