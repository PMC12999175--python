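import numpy as np
import pytest

from rsfc.catalog import default_catalog
from rsfc.synthetic import (
    AcquisitionSpec,
    ArtifactSpec,
    make_correlation_template,
    simulate_subject,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def blind_template(catalog):
    return make_correlation_template("blind_like", catalog, effect_size=0.15)


@pytest.fixture(scope="session")
def clean_recording(blind_template):
    """Artifact-free medium-length recording, shared across tests."""
    acq = AcquisitionSpec(n_frames=400, tr_seconds=0.5, cohort="infant")
    return simulate_subject(blind_template, acq, ArtifactSpec(seed=7))


def random_symmetric(rng, n, scale=1.0):
    a = rng.uniform(-scale, scale, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a
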