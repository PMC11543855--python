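import numpy as np
import pytest

from chromatie import OpticalTrain, SampledGrid


@pytest.fixture(scope="session")
def train_1mm() -> OpticalTrain:
    """The 0.5 mm-aperture, 1 mm-focal hyperboloid design in 2f-2f imaging."""
    return OpticalTrain.two_f(1000.0, 250.0, design_wavelength=530.0)


@pytest.fixture
def grid128() -> SampledGrid:
    return SampledGrid(128, 128, 1.0)


@pytest.fixture
def grid256() -> SampledGrid:
    return SampledGrid(256, 256, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def band_limited_field(grid: SampledGrid, rng, k_max: float = 1.0) -> np.ndarray:
    """Random complex field whose spectrum is confined below ``k_max`` rad/µm."""
    spectrum = np.fft.fft2(
        rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
    )
    spectrum[np.sqrt(grid.k_squared()) > k_max] = 0.0
    amp = np.fft.ifft2(spectrum)
    return amp / np.abs(amp).max()
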