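import numpy as np
import pytest

from dtialps import CohortParams, PhantomSpec, generate_cohort, generate_dwi_phantom, phantom_rois


@pytest.fixture()
def noiseless_spec():
    return PhantomSpec(target_alps=1.80, snr_b0=np.inf)


@pytest.fixture()
def noiseless_phantom(noiseless_spec):
    return generate_dwi_phantom(noiseless_spec), phantom_rois(noiseless_spec)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortParams(n_subjects=60, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    return generate_cohort(CohortParams(n_subjects=50_000, seed=7))
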