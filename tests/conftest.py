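import numpy as np
import pytest

from agscc import synthdata as sd
from agscc.response_surface import fit_response_surface


@pytest.fixture(scope="session")
def truth():
    """The known synthetic response surface all generators draw from."""
    return sd.paperlike_coefficients()


@pytest.fixture(scope="session")
def noiseless_db():
    """A meta-database with (essentially) no noise: exact interpolation case."""
    return sd.gen_meta_database(sd.MetaGenSpec(seed=101, sd=1e-9, rho=0.0))


@pytest.fixture(scope="session")
def noisy_db():
    """A full-size synthetic database at the default study conditions."""
    return sd.gen_meta_database(sd.MetaGenSpec(seed=202))


@pytest.fixture(scope="session")
def fitted(noisy_db):
    return fit_response_surface(noisy_db)


@pytest.fixture(scope="session")
def grids():
    return sd.gen_grids(sd.GridGenSpec(seed=11))


@pytest.fixture(scope="session")
def bau():
    return sd.gen_bau_scenario(seed=7)
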