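import numpy as np
import pytest

from phasebayes.model_core import FourierInteraction


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_interaction(rng, M=None, scale=1.0):
    M = M or int(rng.integers(1, 4))
    return FourierInteraction(
        a=scale * rng.normal(size=M), b=scale * rng.normal(size=M)
    )


@pytest.fixture
def tiny_regression(rng):
    """A small (T=50, P=3) linear-Gaussian instance with known generating
    parameters, used against the dense-quadrature oracle."""
    T, sigma2 = 50, 0.3 ** 2
    F = np.column_stack([np.ones(T), np.cos(rng.uniform(0, 2 * np.pi, T)),
                         np.sin(rng.uniform(0, 2 * np.pi, T))])
    c_true = np.array([1.2, 0.4, -0.7])
    delta = F @ c_true + np.sqrt(sigma2) * rng.standard_normal(T)
    return F, delta
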