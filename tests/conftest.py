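import numpy as np
import pytest

from breathvoc.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact generated cohort shared by read-only tests."""
    config = GeneratorConfig(
        n_case=20, n_control=40, n_features=60, n_discriminant=3,
        effect_log2=2.0, n_contaminants=4, n_ambient_dominant=5, seed=11,
    )
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
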