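import numpy as np
import pytest

from dendtf import (
    BoundaryParams,
    DendriteGeometry,
    KineticScheme,
    MembraneParams,
    MultiExpDistribution,
)


@pytest.fixture(scope="session")
def membrane():
    """Default bistable compartment (steepened Mg2+ blockade, k = 2.5 mV)."""
    return MembraneParams()


@pytest.fixture(scope="session")
def standard_membrane():
    """Same compartment with the standard blockade slope k = 12.5 mV."""
    return MembraneParams(k=12.5)


@pytest.fixture(scope="session")
def opening_full():
    return MultiExpDistribution((0.55, 0.30, 0.15), (0.15, 1.5, 6.0))


@pytest.fixture(scope="session")
def opening_filtered(opening_full):
    return opening_full.filter_and_reweight(0.5)


@pytest.fixture(scope="session")
def burst_full():
    return MultiExpDistribution((0.40, 0.35, 0.25), (0.8, 7.0, 60.0))


@pytest.fixture(scope="session")
def burst_filtered(burst_full):
    return burst_full.filter_and_reweight(2.0)


@pytest.fixture(scope="session")
def boundary12():
    return BoundaryParams.symmetric(12.0, 0.5)


@pytest.fixture(scope="session")
def two_site_geometry():
    """Sites at 200 and 260 um, symmetric decay, lambda = 77 um."""
    return DendriteGeometry((200.0, 260.0), 77.0)


@pytest.fixture(scope="session")
def scheme():
    return KineticScheme()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150810)
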