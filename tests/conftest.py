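import numpy as np
import pytest

from cimexdyn import (
    SITParameters,
    SITState,
    make_environmental_stack,
    make_true_suitability,
    sample_occurrences,
)

# canonical above-threshold parameter set (R0 = 5/3) with known endemic
# equilibrium (S*, I*, T*) = (60, 24, 16) at N = 100
CANON = SITParameters(beta=0.5, gamma=0.1, tau=0.2, alpha=0.3)
N = 100.0


@pytest.fixture
def canon_params() -> SITParameters:
    return CANON


@pytest.fixture
def canon_init() -> SITState:
    return SITState(s=90.0, i=10.0, t=0.0)


@pytest.fixture(scope="session")
def planted_stack():
    """Small covariate stack with a dominant 'temp' signal and its
    occurrences, shared across model tests."""
    stack = make_environmental_stack((60, 60), 4, 4, seed=11,
                                     layer_names=("temp", "humidity", "noise_a", "noise_b"))
    truth = make_true_suitability(stack, {"temp": 2.5, "humidity": 1.0}, intercept=-4.0)
    occ = sample_occurrences(truth, 150, seed=11, species_label="test")
    return stack, truth, occ


def random_valid_params(rng: np.random.Generator, allow_zero_alpha=True) -> SITParameters:
    alpha = float(rng.uniform(0.0 if allow_zero_alpha else 0.05, 1.0))
    return SITParameters(
        beta=float(np.exp(rng.uniform(np.log(0.05), np.log(2.0)))),
        gamma=float(np.exp(rng.uniform(np.log(0.01), np.log(1.0)))),
        tau=float(np.exp(rng.uniform(np.log(0.01), np.log(1.0)))),
        alpha=alpha,
    )


def random_init(rng: np.random.Generator, n: float = N) -> SITState:
    w = rng.dirichlet([2.0, 1.0, 1.0])
    return SITState(s=w[0] * n, i=w[1] * n, t=w[2] * n)
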