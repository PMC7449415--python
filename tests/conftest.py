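import numpy as np
import pytest

from lithicnet import (
    ClassScheme,
    TechnologyMatrix,
    TrainingConfig,
    synthetic_reference_matrix,
)


@pytest.fixture(scope="session")
def surrogate() -> TechnologyMatrix:
    """The fixed synthetic surrogate of the published 92×16 table."""
    return synthetic_reference_matrix()


@pytest.fixture
def scheme3() -> ClassScheme:
    return ClassScheme.three_way()


@pytest.fixture
def scheme2() -> ClassScheme:
    return ClassScheme.two_way()


@pytest.fixture
def toy_matrix() -> TechnologyMatrix:
    """A 6-assemblage, 4-technology table small enough for hand computation."""
    return TechnologyMatrix(
        assemblage_ids=[f"A{i}" for i in range(6)],
        technologies=["T1", "T2", "T3", "T4"],
        presence=np.array(
            [
                [1, 0, 1, 0],
                [1, 1, 0, 0],
                [0, 0, 1, 1],
                [0, 1, 1, 0],
                [1, 0, 0, 1],
                [0, 0, 0, 0],
            ]
        ),
        labels3=["LSA", "LSA", "MIS3&4 MSA", "MIS3&4 MSA", "MIS5 MSA", "MIS5 MSA"],
    )


@pytest.fixture
def fast_config() -> TrainingConfig:
    """A small epoch budget for tests where convergence quality is not the point."""
    return TrainingConfig(max_epochs=40)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def trained_ensemble3(surrogate):
    """A small but fully converged three-way ensemble on the surrogate,
    shared across tests that need realistic trained networks."""
    from lithicnet import train_ensemble

    return train_ensemble(surrogate, ClassScheme.three_way(), 16, seed=13)
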