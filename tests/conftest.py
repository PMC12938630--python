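import numpy as np
import pytest

from cmbdetect import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def quiet_spec():
    """Phantom with all stochastic appearance terms disabled."""
    return PhantomSpec(
        n_cmbs=1,
        n_vessels=0,
        noise_sd=0.0,
        bias_amplitude=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def quiet_phantom(quiet_spec):
    return generate_phantom(quiet_spec)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
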