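import numpy as np
import pytest

from metabonet import GeneratorSpec, derive_phenotypes, sample_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-record default-calibrated synthetic cohort."""
    spec = GeneratorSpec.default(n_subjects=2000, seed=1)
    return sample_cohort(spec)


@pytest.fixture(scope="session")
def small_phenotyped(small_cohort):
    return derive_phenotypes(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
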