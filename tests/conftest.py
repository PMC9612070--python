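import pytest

from pexofusion import FusionGeometry, preset


@pytest.fixture(scope="session")
def dopc():
    """(MonolayerParams, InteractionParams) for the pure DOPC composition."""
    return preset("DOPC")


@pytest.fixture(scope="session")
def dopc_dope():
    """(MonolayerParams, InteractionParams) for the 1:1 DOPC:DOPE mixture."""
    return preset("DOPC_DOPE_1_1")


@pytest.fixture(scope="session")
def mono_geometry():
    """Monolayer-bilayer geometry at the reference separation H0 = 3 nm."""
    return FusionGeometry(mode="monolayer_bilayer", H0=3.0)


@pytest.fixture(scope="session")
def bil_geometry():
    """Bilayer-bilayer geometry at the reference separation H0 = 3 nm."""
    return FusionGeometry(mode="bilayer_bilayer", H0=3.0)
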