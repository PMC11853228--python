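import numpy as np
import pytest

from mslsci.stacks import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stack(frames, wavelength_nm=658.0, **kwargs):
    """Wrap a float/int array as an ImageStack with sane defaults."""
    return ImageStack(frames=np.asarray(frames), wavelength_nm=wavelength_nm,
                      **kwargs)


@pytest.fixture
def exponential_stack(rng):
    """200 independent frames of unit-mean negative-exponential intensity
    (fully developed speckle sampled pixel-independently), scaled into
    camera counts."""
    frames = rng.exponential(scale=1000.0, size=(200, 64, 64))
    return make_stack(np.minimum(frames, 65535))
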