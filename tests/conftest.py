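import numpy as np
import pytest

from pqdseg import make_cohort
from pqdseg.dseg_core import PQSegmentation


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 2 timepoints on a 24^3 grid (~5.6k voxels each)."""
    return make_cohort(3, 2, seed=11, shape=(24, 24, 24))


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """Segmentation fitted on the pooled small cohort."""
    return PQSegmentation.from_cohort(small_cohort).fit()


def random_eigenvalues(rng, n, scale=1e-3):
    """Random sorted-descending positive eigenvalue triples (mm^2/s)."""
    lams = rng.uniform(0.05, 3.0, size=(n, 3)) * scale
    return np.sort(lams, axis=1)[:, ::-1]
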