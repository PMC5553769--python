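import numpy as np
import pytest

from repmix.model import MixtureParams, TestStatTable


def random_mixture_params(rng: np.random.Generator) -> MixtureParams:
    """A random valid parameter set with clearly separated components."""
    pi0 = rng.uniform(0.5, 0.9)
    p1 = rng.uniform(0.2, 0.8) * (1 - pi0)
    return MixtureParams(
        pi=[pi0, p1, 1 - pi0 - p1],
        mu1=rng.uniform(2.5, 6.0, 2),
        mu2=-rng.uniform(2.5, 6.0, 2),
        sigma_g2=rng.uniform(0.05, 0.5),
        sigma_G1_2=rng.uniform(0.05, 0.5),
        sigma_G2_2=rng.uniform(0.05, 0.5),
    )


def random_stats(rng: np.random.Generator, n: int = 50) -> TestStatTable:
    return TestStatTable(
        [f"g{i}" for i in range(n)], rng.normal(0, 3, n), rng.normal(0, 3, n)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def simple_params() -> MixtureParams:
    return MixtureParams(
        pi=[0.8, 0.1, 0.1],
        mu1=[4.0, 4.0],
        mu2=[-4.0, -4.0],
        sigma_g2=0.25,
        sigma_G1_2=0.25,
        sigma_G2_2=0.25,
    )


@pytest.fixture
def small_stats() -> TestStatTable:
    return TestStatTable(
        ["a", "b", "c", "d", "e"],
        [0.0, 4.1, -3.9, 1.2, -0.5],
        [0.1, 3.8, -4.2, -1.1, 0.4],
    )
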