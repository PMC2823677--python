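import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from icmodels import (
    Hyperparameters,
    InteractionNetwork,
    PlantedDesign,
    generate_overlapping_network,
)


@pytest.fixture
def triangle() -> InteractionNetwork:
    """Three nodes, three links forming a triangle."""
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def two_triangles() -> InteractionNetwork:
    """Two disjoint triangles -- the smallest two-module network."""
    return InteractionNetwork.from_edges(
        [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")]
    )


@pytest.fixture
def four_cycle() -> InteractionNetwork:
    """Four nodes in a cycle; small enough for full posterior enumeration."""
    return InteractionNetwork.from_edges(
        [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")]
    )


@pytest.fixture(scope="session")
def planted():
    """One realization of the default planted overlapping-module network."""
    network, truth = generate_overlapping_network(PlantedDesign())
    return network, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def random_state_for(network, hyper: Hyperparameters, seed: int):
    from icmodels.core import init_assignments

    return init_assignments(network, hyper, seed)
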