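import numpy as np
import pytest

from biasfield.phantom import FieldSpec, PhantomSpec, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_sample():
    """Noise-free 16^3 sample for exact-arithmetic tests."""
    pspec = PhantomSpec(shape=(16, 16, 16), noise_sd=0.0, geom_jitter=0.0)
    fspec = FieldSpec(log_amplitude=0.3, correlation_length=4.0)
    return generate_sample(pspec, fspec, seed=7)


@pytest.fixture
def noisy_sample():
    pspec = PhantomSpec(shape=(16, 16, 16), noise_sd=0.01, geom_jitter=0.0)
    fspec = FieldSpec(log_amplitude=0.3, correlation_length=4.0)
    return generate_sample(pspec, fspec, seed=11)
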