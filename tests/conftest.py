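import numpy as np
import pytest

from circaclock import (
    LightProgram,
    Reaction,
    ReactionNetwork,
    Species,
    ThetaVector,
    build_clock_network,
    reference_theta,
)


@pytest.fixture(scope="session")
def theta_ref() -> ThetaVector:
    return reference_theta()


@pytest.fixture(scope="session")
def dark_240() -> LightProgram:
    return LightProgram.dark(240.0)


@pytest.fixture(scope="session")
def clock_dark(theta_ref, dark_240):
    return build_clock_network(theta_ref, dark_240)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def decay_network(k: float = 0.5, x0: int = 1000) -> ReactionNetwork:
    """Pure-decay toy: A -> 0 at rate k."""
    return ReactionNetwork(
        [Species("A")],
        [Reaction("k", reactants={"A": 1}, rate=k)],
        initial_counts={"A": x0},
    )


def birth_death_network(birth: float, death: float, x0: int = 0) -> ReactionNetwork:
    """Immigration-death toy: 0 -> A at `birth`, A -> 0 at `death` per
    molecule; stationary law is Poisson(birth/death)."""
    return ReactionNetwork(
        [Species("A")],
        [Reaction("b", products={"A": 1}, rate=birth),
         Reaction("d", reactants={"A": 1}, rate=death)],
        initial_counts={"A": x0},
    )


def catalytic_network(k_make: float = 2.0, k_decay: float = 1.0,
                      cat0: int = 7, x0: int = 0) -> ReactionNetwork:
    """Catalyst C drives 0 -> A; A decays. C is never consumed."""
    return ReactionNetwork(
        [Species("C"), Species("A")],
        [Reaction("make", products={"A": 1}, catalysts={"C": 1}, rate=k_make),
         Reaction("decay", reactants={"A": 1}, rate=k_decay)],
        initial_counts={"C": cat0, "A": x0},
    )
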