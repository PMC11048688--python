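import numpy as np
import pytest

from eegdem import CohortSpec, WindowSpec, generate_cohort
from eegdem.features import extract_cohort_features


@pytest.fixture(scope="session")
def study_cohort():
    """The scaled-down study cohort: 10 subjects/group, 60 s at 500 Hz."""
    return generate_cohort(CohortSpec(n_per_group=(10, 10, 10), duration_s=60.0, seed=1))


@pytest.fixture(scope="session")
def svd_features_50(study_cohort):
    return extract_cohort_features(study_cohort, WindowSpec(1.0, 0.5), "svd")


@pytest.fixture(scope="session")
def svd_features_90(study_cohort):
    return extract_cohort_features(study_cohort, WindowSpec(1.0, 0.9), "svd")


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for classification mechanics: 6/group, 20 s."""
    return generate_cohort(CohortSpec(n_per_group=(6, 6, 6), duration_s=20.0, seed=2))


@pytest.fixture(scope="session")
def small_svd_features(small_cohort):
    return extract_cohort_features(small_cohort, WindowSpec(1.0, 0.5), "svd")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
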