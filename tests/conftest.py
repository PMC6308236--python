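import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def gaussian_spot_frame(
    spots, snr, shape=(128, 128), bg=200.0, noise_sd=20.0, psf_sigma=1.3, rng=None
):
    """Render Gaussian spots of amplitude snr*noise_sd on a noisy background."""
    img = np.full(shape, float(bg))
    xs = np.arange(shape[1])
    ys = np.arange(shape[0])
    for x, y in spots:
        img += (snr * noise_sd) * np.exp(
            -((ys[:, None] - y) ** 2 + (xs[None, :] - x) ** 2) / (2 * psf_sigma**2)
        )
    if rng is not None and noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)
    return img
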