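import numpy as np
import pytest

import neurogsp as ng
from neurogsp import gsp, synthetic


@pytest.fixture(scope="session")
def tiny_spec():
    """Small cohort shape used across tests: 40 subjects, 20 regions."""
    return ng.CohortSpec(
        n_subjects=40, n_regions=20, n_sessions=2, frames_per_session=80, seed=7
    )


@pytest.fixture(scope="session")
def tiny_sc(tiny_spec):
    scs, coords = synthetic.generate_sc(tiny_spec, noise_level=0.1)
    return scs


@pytest.fixture(scope="session")
def tiny_spectrum(tiny_sc):
    return gsp.spectrum_from_connectome(tiny_sc[0])


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    """Cohort with a continuous target at signal fraction 0.4 on the sd basis."""
    return ng.make_dataset(
        tiny_spec,
        effects=[ng.EffectSpec("score", "sd", 0.4)],
        noise_level=0.1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
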