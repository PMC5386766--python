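import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from radrec.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def table2_cohort():
    """One seeded n=51 cohort at the published group parameters."""
    cohort, truth = generate_cohort(SyntheticConfig(seed=20160531 % 2**31))
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(987654321)
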