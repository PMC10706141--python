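import numpy as np
import pytest

from ctbonetex import (
    SimConfig,
    TextureFeatureExtractor,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-subject cohort shared by feature/regression-level tests."""
    return generate_cohort(SimConfig(n_subjects=30, seed=42))


@pytest.fixture(scope="session")
def small_design(small_cohort):
    """(X 45-feature matrix, bmc, bmd) over all 60 cases of the cohort."""
    ext = TextureFeatureExtractor()
    X = ext.fit_transform([r.volume for r in small_cohort.records])
    bmc = np.array([r.bmc_true for r in small_cohort.records])
    bmd = np.array([r.bmd_true for r in small_cohort.records])
    return X, bmc, bmd


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
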