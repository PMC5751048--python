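"""Shared fixtures: small hand-built and generated heterogeneous networks."""

import numpy as np
import pytest

from hetprop import (
    EntitySubnetwork,
    FixtureSpec,
    HeterogeneousNetwork,
    RelationSubnetwork,
    generate,
)


@pytest.fixture
def toy_abc() -> HeterogeneousNetwork:
    """Three-entity-type network in the style of a worked tool example:
    subnetworks A (3 nodes), B (2), C (3), relations A-B, B-C and A-C."""
    a = EntitySubnetwork("A", ["0", "1", "2"],
                         np.array([[0, 0.5, 0.2],
                                   [0.5, 0, 0.0],
                                   [0.2, 0.0, 0]]))
    b = EntitySubnetwork("B", ["3", "4"],
                         np.array([[0, 0.7], [0.7, 0]]))
    c = EntitySubnetwork("C", ["5", "6", "7"],
                         np.array([[0, 0.3, 0.0],
                                   [0.3, 0, 0.6],
                                   [0.0, 0.6, 0]]))
    ab = RelationSubnetwork("A", "B",
                            np.array([[0.9, 0.0],
                                      [0.0, 0.4],
                                      [0.0, 0.0]]))
    bc = RelationSubnetwork("B", "C",
                            np.array([[0.8, 0.0, 0.0],
                                      [0.0, 0.5, 0.0]]))
    ac = RelationSubnetwork("A", "C",
                            np.array([[0.6, 0.0, 0.0],
                                      [0.0, 0.7, 0.0],
                                      [0.0, 0.0, 0.3]]))
    return HeterogeneousNetwork([a, b, c], [ab, bc, ac])


@pytest.fixture
def planted_chain() -> HeterogeneousNetwork:
    """Small generated chain fixture with planted associations."""
    return generate(planted_chain_spec())


def planted_chain_spec(seed: int = 3) -> FixtureSpec:
    return FixtureSpec(
        sizes=(8, 8, 8),
        planted=((0, 2, 0.9), (1, 5, 0.8), (4, 7, 0.8)),
        seed=seed,
    )


def random_entity(n: int, rng: np.random.Generator,
                  density: float = 0.4, name: str = "X") -> EntitySubnetwork:
    """Random symmetric non-negative subnetwork for oracle comparisons."""
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, k=1)
    w = w + w.T
    return EntitySubnetwork(name, [str(i) for i in range(n)], w)
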