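import pytest

from iscatflow.config import NoiseConfig, OpticsConfig
from iscatflow.scenarios import analyze_channel_scan, render_channel_scan


@pytest.fixture(scope="session")
def small_optics():
    return OpticsConfig(frame_side=256)


@pytest.fixture(scope="session")
def quiet_noise():
    """Default instrument noise: 4e6 photons/px per averaged frame."""
    return NoiseConfig(camera_offset=100.0)


@pytest.fixture(scope="session")
def noiseless():
    return NoiseConfig(photon_budget_per_avg_frame=0.0, camera_offset=0.0, read_noise=0.0)


@pytest.fixture(scope="session")
def mixed_scan_result():
    """Shared mid-size mixed background+signal scan, analysed once.

    3x4 grid of 512 px tiles at the default photon budget; background
    3.0 and signal 0.5 per 100 um^2.
    """
    out = []
    for seed in range(5):
        sc = render_channel_scan(optics=OpticsConfig(frame_side=512),
                                 n_rows=3, n_cols=4, background_density=3.0,
                                 signal_density=0.5, seed=seed)
        out.append((sc, analyze_channel_scan(sc)))
    return out
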