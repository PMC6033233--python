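import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from guidescout.enzymes import get_enzyme
from guidescout.fixtures import synth_genome

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cas9():
    return get_enzyme("spcas9ngg")


@pytest.fixture(scope="session")
def cas9_nag():
    return get_enzyme("spcas9ngg-nag")


@pytest.fixture(scope="session")
def cpf1():
    return get_enzyme("cpf1")


@pytest.fixture(scope="session")
def small_genome():
    """20 kb two-contig random genome shared by read-only tests."""
    return synth_genome(seed=101, length=20_000, gc=0.5, n_contigs=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_site(rng, enzyme, pam=None):
    """One concrete random site string for ``enzyme`` in guide orientation."""
    from guidescout.enzymes import IUPAC

    proto = "".join(rng.choice(list("ACGT"), enzyme.protospacer_len))
    if pam is None:
        pattern = enzyme.pams[int(rng.integers(len(enzyme.pams)))]
        pam = "".join(IUPAC[s][int(rng.integers(len(IUPAC[s])))] for s in pattern)
    return enzyme.site_string(proto, pam)
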