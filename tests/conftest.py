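import numpy as np
import pytest

from usncal import PhantomConfig, make_ground_truth_calibration


@pytest.fixture
def native_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture
def quiet_config() -> PhantomConfig:
    """Phantom with tracking noise switched off."""
    return PhantomConfig(tracking_noise_pos_mm=0.0, tracking_noise_rot_deg=0.0)


@pytest.fixture
def ground_truth(native_config):
    return make_ground_truth_calibration(native_config, np.random.default_rng(42))
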