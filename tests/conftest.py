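import dataclasses

import numpy as np
import pytest

from redsnn import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-spec cohort, 300 patients, seed 7."""
    spec = dataclasses.replace(default_cohort_spec(n_patients=300), seed=7)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
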