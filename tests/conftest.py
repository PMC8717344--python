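import numpy as np
import pytest

from gapcal.gapsim import ClimateNormals, SiteConditions, SpeciesParams, run_stand
from gapcal.harness import default_normals, default_site, default_species


@pytest.fixture(scope="session")
def species_defaults() -> dict[str, SpeciesParams]:
    return default_species()


@pytest.fixture(scope="session")
def site() -> SiteConditions:
    return default_site()


@pytest.fixture(scope="session")
def normals() -> ClimateNormals:
    return default_normals()


@pytest.fixture(scope="session")
def small_stand(species_defaults, site, normals):
    """An 80-year two-species stand used by several test modules."""
    return run_stand(species_defaults, site, normals, years=80, seed=123)


@pytest.fixture(scope="session")
def long_stand(species_defaults, site, normals):
    """A 160-year stand with substantial mortality history."""
    return run_stand(species_defaults, site, normals, years=160, seed=7)
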