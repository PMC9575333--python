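import numpy as np
import pytest

from rdepth import BandConfig, make_phantom
from rdepth.synth import CohortSpec, PhantomSpec, make_cohort


@pytest.fixture(scope="session")
def default_phantom():
    """Default-geometry phantom: all 12 annular bands lie inside the brain."""
    return make_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_phantom():
    """A small, quick phantom; distal bands truncate at the brain edge."""
    spec = PhantomSpec(
        shape=(36, 36, 36),
        spacing=(2.0, 2.0, 2.0),
        necrotic_radius_mm=3.0,
        enhancing_radius_mm=6.0,
        peritumoral_radius_mm=9.0,
        brain_semiaxes_mm=(32.0, 32.0, 32.0),
        seed=3,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def recovery_cohorts():
    """Train/test feature+survival tables with amplitude-driven hazard."""
    phantom = PhantomSpec(seed=0)
    train = make_cohort(phantom, CohortSpec(n=120, beta=1.5, seed=101))
    test = make_cohort(phantom, CohortSpec(n=120, beta=1.5, seed=202))
    return train, test


@pytest.fixture(scope="session")
def null_cohorts():
    """Train/test tables with no amplitude-hazard linkage (beta = 0)."""
    phantom = PhantomSpec(seed=0)
    train = make_cohort(phantom, CohortSpec(n=120, beta=0.0, seed=303))
    test = make_cohort(phantom, CohortSpec(n=120, beta=0.0, seed=404))
    return train, test


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
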