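import warnings

import numpy as np
import pytest

from betaconn.cohort import GroundTruth, generate_cohort
from betaconn.networks import DEFAULT_ROIS

warnings.filterwarnings("ignore", message="Maximum Likelihood optimization")


@pytest.fixture(scope="session")
def rois():
    return DEFAULT_ROIS


@pytest.fixture(scope="session")
def roi_labels():
    return [s.name for s in DEFAULT_ROIS]


@pytest.fixture(scope="session")
def roi_networks():
    return [s.network for s in DEFAULT_ROIS]


@pytest.fixture(scope="session")
def truth():
    return GroundTruth()


@pytest.fixture(scope="session")
def small_bold_cohort():
    """Two full-BOLD subjects at default generator settings."""
    return generate_cohort(2, GroundTruth(), seed=123, mode="bold")


@pytest.fixture(scope="session")
def beta_cohort():
    """Fifty ROI-level subjects for inference tests."""
    return generate_cohort(50, GroundTruth(), seed=202, mode="beta")


@pytest.fixture
def rng():
    return np.random.default_rng(99)
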