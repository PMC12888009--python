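import pytest
from hypothesis import settings

from venomics import VenomComposition, reference

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return dict(reference.FAMILY_MASSES_DA)


@pytest.fixture(scope="session")
def compositions(registry):
    """Published family-level compositions for all seven species."""
    return {
        sp: VenomComposition(sp, dict(masses), registry)
        for sp, masses in reference.MASS_PERCENT.items()
    }


@pytest.fixture(scope="session")
def matto(compositions):
    return compositions["mattogrossensis"]
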