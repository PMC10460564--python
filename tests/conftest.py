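import numpy as np
import pytest

from smmira import (
    AssociationMatrix,
    EntityIndex,
    FixtureSpec,
    NIConfig,
    RBMConfig,
    SimilarityMatrix,
    generate_fixture,
)


@pytest.fixture
def toy_assoc() -> AssociationMatrix:
    """2x2 identity association pattern over {s1,s2} x {m1,m2}."""
    return AssociationMatrix(
        sms=EntityIndex.from_ids(["s1", "s2"]),
        mirnas=EntityIndex.from_ids(["m1", "m2"]),
        A=np.array([[1, 0], [0, 1]]),
    )


@pytest.fixture
def toy_sim_sm(toy_assoc) -> SimilarityMatrix:
    return SimilarityMatrix(
        entities=toy_assoc.sms, S=np.array([[1.0, 0.6], [0.6, 1.0]])
    )


@pytest.fixture
def toy_sim_mirna(toy_assoc) -> SimilarityMatrix:
    return SimilarityMatrix(
        entities=toy_assoc.mirnas, S=np.array([[1.0, 0.6], [0.6, 1.0]])
    )


@pytest.fixture(scope="session")
def block_fixture():
    """The standard planted-block dataset: 20 SMs x 30 miRNAs, 2 blocks."""
    return generate_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def noiseless_fixture():
    """Degenerate block fixture: dense within, empty across, exact sims."""
    spec = FixtureSpec(
        within_density=1.0,
        between_density=0.0,
        sim_noise_sd=0.0,
        seed=7,
    )
    return generate_fixture(spec)


@pytest.fixture
def fast_rbm_cfg() -> RBMConfig:
    """Small, quick RBM settings for fixture-scale training."""
    return RBMConfig(hidden_units=8, epochs=30, batch_size=10, seed=3)


@pytest.fixture
def regime_ni_cfg() -> NIConfig:
    """Threshold grid strictly between the fixture's block similarities."""
    return NIConfig(grid=(0.25, 0.3, 0.35, 0.4, 0.45, 0.5), sigma_upper=0.5)


def random_assoc(rng: np.random.Generator, ns: int, nm: int, p: float = 0.3):
    A = (rng.random((ns, nm)) < p).astype(np.int8)
    # keep at least one association so the matrix is usable everywhere
    if A.sum() == 0:
        A[rng.integers(ns), rng.integers(nm)] = 1
    return AssociationMatrix(
        sms=EntityIndex.from_ids([f"s{i}" for i in range(ns)]),
        mirnas=EntityIndex.from_ids([f"m{j}" for j in range(nm)]),
        A=A,
    )


def random_similarity(rng: np.random.Generator, entities: EntityIndex):
    n = len(entities)
    raw = rng.random((n, n))
    S = (raw + raw.T) / 2
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(entities=entities, S=S)
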