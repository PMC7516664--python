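import numpy as np
import pytest

import rhythmflow as rf


@pytest.fixture
def rng():
    return np.random.default_rng(20_2026)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-pair cohort with default (expertise-linked) coupling, both sessions."""
    return rf.generate_cohort(6, seed=11)


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort):
    return rf.build_cohort_table(small_cohort)
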