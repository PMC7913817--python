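import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from opqct.calibration import calibrate_scan
from opqct.synth import generate_scan, identity_phantom, scaled_specs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specs():
    """Default full-size (geometry, body, phantom) triple."""
    return scaled_specs(1.0)


@pytest.fixture(scope="session")
def small_specs():
    """Uniformly scaled-down anatomy for fast smoke tests."""
    return scaled_specs(0.7)


@pytest.fixture(scope="session")
def clean_scan(specs):
    """Noise-free, offset-free scan with an identity calibration line."""
    geometry, body, _ = specs
    phantom = identity_phantom()
    densities = {lv: 150.0 for lv in __import__("opqct").LEVELS}
    volume, truth = generate_scan(
        geometry, body, phantom, densities, hu_offset=0.0, noise_sd=0.0, seed=1
    )
    return volume, truth, phantom


@pytest.fixture(scope="session")
def noisy_scan(specs):
    """Scan under the default study conditions (noise + contrast offset)."""
    geometry, body, phantom = specs
    volume, truth = generate_scan(
        geometry, body, phantom, hu_offset=35.0, noise_sd=20.0, seed=7
    )
    return volume, truth, phantom


@pytest.fixture(scope="session")
def calibrated_noisy_scan(noisy_scan):
    volume, truth, phantom = noisy_scan
    return volume, truth, calibrate_scan(volume, phantom)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
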