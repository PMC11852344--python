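import numpy as np
import pytest

from flow4d import AnalysisConfig
from flow4d.phantom import default_waveform, make_tube_phantom, tube_spec


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def waveform():
    return default_waveform()


@pytest.fixture(scope="session")
def parabolic_phantom(cfg, waveform):
    """Noise-free parabolic tube: R = 10 mm, vmax = 1 m/s, clinical grid."""
    spec = tube_spec(10.0, 1.0 * waveform, profile_exponent=2.0)
    field, mag, masks, truth = make_tube_phantom(spec, cfg)
    return spec, field, mag, masks, truth


@pytest.fixture()
def small_field():
    """Tiny synthetic velocity field for contract tests (no tube geometry)."""
    rng = np.random.default_rng(0)
    data = rng.normal(0, 0.1, size=(6, 6, 6, 4, 3))
    from flow4d import VelocityField4D

    return VelocityField4D(
        data=data,
        spacing=np.array([2.0, 2.0, 2.0]),
        frame_duration=100.0,
        venc=1.5,
        rr_interval=400.0,
    )
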