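import numpy as np
import pytest

from egodyn import (
    Alter,
    CultureLabel,
    EgoNetwork,
    RelationalDomain,
    generate_network,
)

A = CultureLabel.CULTURE_A
B = CultureLabel.CULTURE_B


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def complete_half_half(rng):
    """8 alters, 4 of each culture, fully connected (28 ties)."""
    return generate_network(8, 4, 28, rng=rng)


@pytest.fixture
def tie_free_all_a(rng):
    """8 culture-A alters, no ties."""
    return generate_network(8, 8, 0, rng=rng)


@pytest.fixture
def tiny_triangle():
    """Hand-built: A-alters {0, 1}, B-alter {2}, ties {(0,1), (0,2)}."""
    return EgoNetwork(
        alters=(Alter(0, A), Alter(1, A), Alter(2, B)),
        ties=frozenset({(0, 1), (0, 2)}),
    )


@pytest.fixture
def two_alter_pair():
    """One A alter, one B alter, no tie between them."""
    return EgoNetwork(alters=(Alter(0, A), Alter(1, B)), ties=frozenset())


def make_domain_network(n_culture_a=8, ties=()):
    """8-alter network with domains: roster slots 0-3 FRIEND, 4-7 COLLEAGUE."""
    alters = tuple(
        Alter(
            i,
            A if i < n_culture_a else B,
            RelationalDomain.FRIEND if i < 4 else RelationalDomain.COLLEAGUE,
        )
        for i in range(8)
    )
    return EgoNetwork(alters=alters, ties=frozenset(ties))
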