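import numpy as np
import pytest

from holotrack.config import OpticalConfig


@pytest.fixture(scope="session")
def optics():
    """The reference imaging geometry: 512 px ↔ 360 μm, 642 nm, NA 0.5."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def optics_small():
    """Quarter-size geometry for fast propagation round trips."""
    return OpticalConfig(frame_width=128, frame_height=128, chamber_depth=100.0)


@pytest.fixture(scope="session")
def optics_medium():
    return OpticalConfig(frame_width=256, frame_height=256, chamber_depth=280.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def bandlimited_field(optics, rng, f_frac=0.5):
    """Random complex field with spectrum confined to f < f_frac × (1/λ_eff)."""
    import scipy.fft as fft

    ny, nx = optics.shape
    spec = rng.normal(size=(ny, nx)) + 1j * rng.normal(size=(ny, nx))
    fx = fft.fftfreq(nx, d=optics.pixel_pitch)[np.newaxis, :]
    fy = fft.fftfreq(ny, d=optics.pixel_pitch)[:, np.newaxis]
    cutoff = f_frac / optics.wavelength_eff
    spec[fx**2 + fy**2 >= cutoff**2] = 0.0
    return fft.ifft2(spec)
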