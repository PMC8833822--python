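import numpy as np
import pytest

from genedose.kinetics import GeneKinetics


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


def random_kinetics(rng, n, n_cap=50.0):
    """Random valid kinetics with N <= n_cap (tractable for brute-force oracles)."""
    out = []
    for _ in range(n):
        rho = rng.uniform(0.05, 1.0)
        N = rng.uniform(0.5, n_cap)
        eps = 10.0 ** rng.uniform(-1.2, 1.5)
        A = rng.uniform(0.02, 0.98)
        out.append(
            GeneKinetics(k=N * rho, rho=rho, f=A * eps * rho, h=(1 - A) * eps * rho)
        )
    return out


@pytest.fixture(scope="session")
def kinetics_grid(rng):
    """25 random parameter sets with N <= 50."""
    return random_kinetics(rng, 25)


@pytest.fixture(scope="session")
def make_random_kinetics():
    """Factory fixture exposing the random-kinetics generator."""
    return random_kinetics
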