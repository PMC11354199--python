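import numpy as np
import pytest

from ciliafreq import Region, SimConfig, simulate_cilia_stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_sine_stack(
    cbf_hz=10.0,
    fps=500.0,
    n_frames=1000,
    shape=(32, 32),
    mask=("rect", 8, 8, 16, 16),
    amplitude=20.0,
    noise_sigma=0.0,
    wavelength_px=np.inf,
    seed=0,
    quantize=False,
    background=100.0,
    drift=None,
):
    """Small noiseless-by-default synthetic recording plus its ground truth."""
    cfg = SimConfig(
        fps=fps,
        n_frames=n_frames,
        height=shape[0],
        width=shape[1],
        regions=[
            Region(mask, cbf_hz=cbf_hz, amplitude=amplitude, wavelength_px=wavelength_px)
        ],
        noise_sigma=noise_sigma,
        seed=seed,
        quantize_output=quantize,
        background=background,
        drift=drift,
    )
    return simulate_cilia_stack(cfg)


@pytest.fixture
def sine_stack():
    """Noiseless on-grid 10 Hz recording, 500 fps, 1000 frames."""
    return make_sine_stack()


@pytest.fixture
def textured_background():
    """Static textured field — what translation registration locks onto."""
    return np.random.default_rng(7).uniform(60.0, 160.0, (48, 48))
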