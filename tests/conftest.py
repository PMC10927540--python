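import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from mukiss.geometry import DeviceGeometry, FlowConfig
from mukiss.flow import build_field, compute_envelope
from mukiss.imaging import NoiseModel, PSFModel

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def narrow_pair():
    """1 μm aperture pair at rim-touching separation."""
    return DeviceGeometry(
        aperture_inner_diameter_inj=1.0,
        aperture_inner_diameter_asp=1.0,
        wall_thickness=1.0,
    )


@pytest.fixture(scope="session")
def wide_pair():
    """6 μm aperture pair (pulled-pipette device)."""
    return DeviceGeometry(
        aperture_inner_diameter_inj=6.0,
        aperture_inner_diameter_asp=6.0,
        wall_thickness=1.0,
    )


@pytest.fixture(scope="session")
def confined_flow():
    return FlowConfig(Q_inj=0.3, Q_asp=1.0)


@pytest.fixture(scope="session")
def narrow_envelope(narrow_pair, confined_flow):
    """Shared small envelope for the 1 μm device (kept cheap)."""
    return compute_envelope(narrow_pair, confined_flow, n_streamlines=300, seed=2)


@pytest.fixture(scope="session")
def wide_field(wide_pair):
    return build_field(wide_pair, FlowConfig(Q_inj=0.16, Q_asp=0.16 / 0.3))


@pytest.fixture(scope="session")
def psf():
    return PSFModel.from_optics(488.0, 1.0)


@pytest.fixture(scope="session")
def fixture_noise():
    return NoiseModel(read_sd=2.0, background=5.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
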