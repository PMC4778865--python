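import numpy as np
import pytest

from betasurrogacy import OccurrenceMatrix


def random_occurrence(rng: np.random.Generator, n_sites: int, n_species: int,
                      density: float = 0.35) -> OccurrenceMatrix:
    """Random boolean community with no empty rows or columns."""
    while True:
        presence = rng.random((n_sites, n_species)) < density
        if presence.any(axis=1).all() and presence.any(axis=0).all():
            break
    return OccurrenceMatrix([f"s{i}" for i in range(n_sites)],
                            [f"sp{j}" for j in range(n_species)], presence)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_community(rng):
    return random_occurrence(rng, 25, 18)
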