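import numpy as np
import pytest

from sagkit import synthetic as sy


@pytest.fixture(scope="session")
def small_genome():
    return sy.simulate_genome(10_000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def medium_genome():
    return sy.simulate_genome(100_000, gc=0.5, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def markov_se(p: float, a: float, b: float, length: int) -> float:
    """Std. error of the mean of a stationary two-state chain over `length` sites.

    Lag-k autocorrelation is (1-a-b)^k, so the long-run variance factor is
    (1+rho)/(1-rho) with rho = 1-a-b.
    """
    rho = 1.0 - a - b
    factor = (1.0 + rho) / (1.0 - rho)
    return float(np.sqrt(p * (1 - p) * factor / length))
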