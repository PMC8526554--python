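import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dynstates.simulate import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20210729)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact 6-subject cohort (full-length scans) shared across tests."""
    spec = CohortSpec(n_subjects=6)
    return generate_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects with short scans, for fast pipeline-level tests."""
    spec = CohortSpec(n_subjects=4, n_timepoints=120)
    return generate_cohort(spec, seed=5)
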