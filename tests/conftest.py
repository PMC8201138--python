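import numpy as np
import pytest

from trienenmr.synthetic import SurrogateParams, TrieneSpec, build_triene_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(20210607)


@pytest.fixture(scope="session")
def hexatriene_z():
    """Planar (Z)-1,3,5-hexatriene (central double bond cis)."""
    return build_triene_geometry(TrieneSpec(pattern=("E", "Z", "E")))


@pytest.fixture(scope="session")
def hexatriene_e():
    """Planar all-trans 1,3,5-hexatriene."""
    return build_triene_geometry(TrieneSpec(pattern=("E", "E", "E")))


@pytest.fixture
def quiet_params():
    return SurrogateParams(noise_sd=0.0, seed=0)
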