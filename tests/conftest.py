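import dataclasses

import pytest

from avitherm import load_parameters


@pytest.fixture(scope="session")
def waxbill():
    """Packaged default parameterization (morphology, physiology, constants)."""
    return load_parameters()


@pytest.fixture(scope="session")
def morph(waxbill):
    return waxbill[0]


@pytest.fixture(scope="session")
def phys(waxbill):
    return waxbill[1]


@pytest.fixture(scope="session")
def summer_phys(phys):
    """Night physiology with the summer basal rate used for TNZ work."""
    return dataclasses.replace(phys, bmr_W=0.20)
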