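import numpy as np
import pytest

from debipm import FeedingRegime, species_preset


@pytest.fixture(scope="session")
def orchestia():
    return species_preset("orchestia_gammarellus")


@pytest.fixture(scope="session")
def manta():
    return species_preset("manta_alfredi")


@pytest.fixture(scope="session")
def orchestia_regime():
    """White-noise study regime for the amphipod, low feeding variability."""
    return FeedingRegime(p=0.5, q=0.5, EY_low=0.4, EY_high=1.0, sigma_Y=0.1)


@pytest.fixture(scope="session")
def manta_regime():
    return FeedingRegime(p=0.5, q=0.5, EY_low=0.5, EY_high=0.9, sigma_Y=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(20190731)
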