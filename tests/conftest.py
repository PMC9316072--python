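import numpy as np
import pytest

from ecshock import GeneratorConfig, build_feature_table, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Eight-subject default cohort shared across read-only tests."""
    return generate_cohort(8, GeneratorConfig(), seed=101)


@pytest.fixture(scope="session")
def feature_table(small_cohort):
    return build_feature_table(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
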