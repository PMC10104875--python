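import numpy as np
import pytest


@pytest.fixture
def gaussian_frame():
    """Factory for noiseless frames with 2-D Gaussian spots (psf sd 2 px)."""

    def make(centers, amp_photons=100.0, shape=(18, 160), sigma=2.0, background=0.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        frame = np.full(shape, float(background))
        for (x, y) in centers:
            frame += amp_photons / (2 * np.pi * sigma**2) * np.exp(
                -(((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
            )
        return frame

    return make
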