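import numpy as np
import pytest

from natgrad.neuron import (
    AfferentConfig,
    RectifiedQuadraticTransfer,
    SigmoidTransfer,
    SynapticKernel,
)

# the formula-level kernel used in worked examples: unit scale, time
# constants quoted as plain numbers (10, 3) — the algebra is unit-agnostic
FORMULA_KERNEL = SynapticKernel(epsilon0=1.0, tau_m=10.0, tau_s=3.0)

# the simulation kernel: integral 1 mV*s, tau_m = 10 ms, tau_s = 3 ms
SIM_KERNEL = SynapticKernel()


@pytest.fixture
def kernel():
    return SIM_KERNEL


@pytest.fixture
def sigmoid():
    return SigmoidTransfer()


@pytest.fixture
def quadratic():
    return RectifiedQuadraticTransfer(theta=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_afferents(kernel):
    rates = np.r_[np.full(5, 10.0), np.full(5, 50.0)]
    return AfferentConfig(rates=rates, kernel=kernel)


def random_afferents(rng, n, kernel=SIM_KERNEL, lo=5.0, hi=55.0):
    return AfferentConfig(rates=rng.uniform(lo, hi, n), kernel=kernel)
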