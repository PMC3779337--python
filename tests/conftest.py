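"""Shared fixtures: communities, constants, and fast solver settings."""

from __future__ import annotations

import numpy as np
import pytest

import allomweb as aw
from allomweb.community import Community, Species


@pytest.fixture(scope="session")
def fixed() -> aw.FixedAllometry:
    return aw.FixedAllometry.default()


@pytest.fixture(scope="session")
def fixture_community() -> Community:
    return aw.load_fixture_community()


@pytest.fixture(scope="session")
def fit_settings() -> aw.SimulationSettings:
    return aw.SimulationSettings.fitting_profile()


@pytest.fixture(scope="session")
def reference_parameters() -> aw.FreeParameters:
    return aw.FreeParameters(**aw.synth.FIXTURE_REFERENCE)


def make_species(i: int, category: str, mass: float, density: float = 1.0) -> Species:
    return Species(id=f"s{i}", name=f"species {i}", body_mass=mass,
                   observed_density=density, category=category)


def single_producer_community(mass: float = 1e-12, density: float = 1e6
                              ) -> Community:
    return Community(
        label="one-producer",
        species=(make_species(0, aw.PRODUCER, mass, density),),
        links=frozenset(),
    )


def pair_community(
    m_producer: float = 1e-12,
    m_consumer: float = 1e-8,
    n_producer: float = 1e6,
    n_consumer: float = 1e2,
) -> Community:
    """One producer feeding one invertebrate consumer."""
    return Community(
        label="pair",
        species=(
            make_species(0, aw.PRODUCER, m_producer, n_producer),
            make_species(1, aw.INVERTEBRATE, m_consumer, n_consumer),
        ),
        links=frozenset({("s0", "s1")}),
    )


def random_web(rng: np.random.Generator, n_producers: int = 2,
               n_consumers: int = 3) -> Community:
    """A small random community: every consumer eats >= 1 smaller species."""
    species = []
    masses = np.sort(rng.uniform(-13, -11, n_producers))
    for i, lm in enumerate(masses):
        species.append(make_species(i, aw.PRODUCER, 10.0 ** lm,
                                    10.0 ** rng.uniform(4, 8)))
    cmasses = np.sort(rng.uniform(-10, -7, n_consumers))
    for k, lm in enumerate(cmasses):
        i = n_producers + k
        cat = aw.INVERTEBRATE if rng.random() < 0.8 else aw.VERTEBRATE
        species.append(make_species(i, cat, 10.0 ** lm,
                                    10.0 ** rng.uniform(0, 4)))
    links = set()
    for k in range(n_consumers):
        j = n_producers + k
        smaller = list(range(j))
        chosen = rng.choice(smaller, size=rng.integers(1, len(smaller) + 1),
                            replace=False)
        for i in chosen:
            links.add((f"s{i}", f"s{j}"))
    return Community(label="random", species=tuple(species),
                     links=frozenset(links))
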