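import numpy as np
import pytest
from hypothesis import settings

from shiftsense.synthetic import default_model_spec, simulate_state_pair

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

# The bond-length-change pattern used for recovery exercises, at the pm scale
# of photoproduct formation (shortenings/lengthenings of order 10-20 pm).
RECOVERY_DELTA_PM = (-17.0, 5.0, -14.0, 0.0, 2.0, 16.0)


@pytest.fixture(scope="session")
def square_noiseless_pair():
    """Noiseless 6x6 dataset: exact linear shifts, known delta-d truth."""
    spec = default_model_spec("square", seed=1, sigma_d_A=0.02, sigma_shift_ppm=0.0)
    dd = dict(zip(spec.bond_labels, RECOVERY_DELTA_PM))
    return simulate_state_pair(spec, dd, 1000, transition_name="Pr->Pg-like")


@pytest.fixture(scope="session")
def square_noisy_pair():
    spec = default_model_spec("square", seed=3, sigma_d_A=0.02, sigma_shift_ppm=0.5)
    dd = dict(zip(spec.bond_labels, RECOVERY_DELTA_PM))
    return simulate_state_pair(spec, dd, 1000, transition_name="noisy")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
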