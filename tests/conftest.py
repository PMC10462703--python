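import numpy as np
import pytest

from spectrakin.io import load_gvalues, load_network, packaged_path


@pytest.fixture
def rng():
    return np.random.default_rng(20230828)


@pytest.fixture(scope="session")
def water_network():
    """The shipped representative radiolysis network (8 species, 12 reactions)."""
    return load_network(
        packaged_path("species_water_representative.csv"),
        packaged_path("reactions_water_representative.csv"),
    )


@pytest.fixture(scope="session")
def alpha_gvalues():
    return load_gvalues(packaged_path("gvalues_alpha_representative.csv"))


ALL_FAMILIES = [
    ("sine", "dirichlet", "neumann"),
    ("cosine", "neumann", "dirichlet"),
    ("sine", "dirichlet", "dirichlet"),
    ("cosine", "neumann", "neumann"),
    ("radial-sine", "dirichlet", "dirichlet"),
    ("radial-sine", "dirichlet", "neumann"),
]
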