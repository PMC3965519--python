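import pytest

import plmotion as plm


@pytest.fixture(scope="session")
def params():
    return plm.REFERENCE_PARAMS


@pytest.fixture(scope="session")
def trace(params):
    """Reference 1g solution, two periods at the 10 kHz generation rate."""
    return plm.solve_pendulum(params)


@pytest.fixture(scope="session")
def family(params):
    """The 21-profile velocity family at the reference parameters."""
    return plm.build_family(params)


@pytest.fixture(scope="session")
def geom():
    return plm.DisplayGeometry()
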