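import numpy as np
import pytest

from oculodce.phantom import PhantomSpec, simulate_study


@pytest.fixture(scope="session")
def quiet_study():
    """Noiseless, motionless default-parameter study shared across tests."""
    spec = PhantomSpec(shape=(48, 42, 20), n_dynamics=125, noise_sigma=0.0, seed=11)
    return simulate_study(spec, with_motion=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
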