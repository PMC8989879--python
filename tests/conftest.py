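import numpy as np
import pytest

from tautraj.gmlvq import GMLVQ
from tautraj.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """60/class cohort for fast classifier-level tests."""
    return generate_cohort(SyntheticConfig(n_stable=60, n_declining=60,
                                           n_acs=60, seed=11))


@pytest.fixture(scope="session")
def trained_model(small_cohort):
    return GMLVQ.from_dataframe(small_cohort.cohort_table).fit(seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 250 subjects per class, seed 0."""
    return generate_cohort(SyntheticConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
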