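import numpy as np
import pytest

from draize.simulate import PROFILES, generate_cohort, worked_example_fixtures


@pytest.fixture(scope="session")
def worked_examples():
    return worked_example_fixtures()


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic mixed cohort covering every category."""
    spec = {
        "nocat_co0": 4,
        "nocat_cogt0_star": 2,
        "cat2a_co": 3,
        "cat2b_conj": 2,
        "cat1_sev_co": 2,
        "cat1_pers_co_minority": 2,
        "cat1_co4": 1,
        "scnm_early_term": 1,
    }
    return generate_cohort(spec, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
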