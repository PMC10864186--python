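import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter

from cafi.core_io import ImageSequence


def make_texture(size: int = 160, seed: int = 0) -> np.ndarray:
    """A smooth, non-periodic-looking random texture on [0, 1]."""
    rng = np.random.default_rng(seed)
    base = gaussian_filter(rng.random((size, size)), 3, mode="wrap")
    return (base - base.min()) / np.ptp(base)


def translating_sequence(
    shift_per_frame: float,
    n_frames: int = 9,
    size: int = 160,
    seed: int = 0,
    direction: tuple[float, float] = (0.3, 1.0),
) -> ImageSequence:
    """A texture translating rigidly by ``shift_per_frame`` pixels per frame.

    Shifts are applied in Fourier space, so any fractional displacement is
    exact and the analytic in-between frame is available for any time.
    """
    base = make_texture(size, seed)
    spectrum = np.fft.fft2(base)
    frames = []
    for i in range(n_frames):
        d = shift_per_frame * i
        shifted = np.fft.ifft2(
            fourier_shift(spectrum, (direction[0] * d, direction[1] * d))
        )
        frames.append(np.real(shifted))
    return ImageSequence(frames=np.stack(frames))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
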