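import pytest
from hypothesis import settings

import phylogp as pg

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True, print_blob=False
)
settings.load_profile("ci")


@pytest.fixture
def two_tip():
    return pg.read_newick("(A:1,B:1):0;")


@pytest.fixture
def three_tip():
    return pg.read_newick("((A:1,B:2):0.5,C:3):0;")


@pytest.fixture
def table1_gammas():
    return pg.TABLE1_GAMMAS


def random_gamma(rng, lmax=1.0):
    """A random, broadly scaled hyperparameter triple."""
    return pg.HyperParams(
        sigma_f=float(rng.uniform(0.2, 3.0)),
        ell=float(rng.uniform(0.05, 2.0) * lmax),
        sigma_n=float(rng.uniform(0.0, 1.5)),
    )
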