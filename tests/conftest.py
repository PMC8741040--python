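import numpy as np
import pytest

from nucdhl.types import EllipseNucleus, NucleusImage, RenderStyle


@pytest.fixture
def clean_style():
    """Renderer style with no noise, no blur, no background gradient."""
    return RenderStyle(psf_sigma=0.0, noise_sd=0.0,
                       background_gradient_amplitude=0.0)


@pytest.fixture
def noisy_style():
    return RenderStyle()


@pytest.fixture
def example_nucleus():
    return EllipseNucleus(a=5.0, b=3.0, cx=0.5, cy=-0.5, theta=0.7,
                          label="cancer", stain="laminA")


@pytest.fixture
def random_ellipses():
    """200 random ellipses with aspect ratio up to 10."""
    rng = np.random.default_rng(42)
    b = rng.uniform(0.5, 5.0, size=200)
    aspect = rng.uniform(1.0, 10.0, size=200)
    return [EllipseNucleus(a=float(bb * asp), b=float(bb))
            for bb, asp in zip(b, aspect)]


def make_image(pixels, pixel_size=0.35, **kw) -> NucleusImage:
    return NucleusImage(pixels=np.asarray(pixels), pixel_size=pixel_size, **kw)
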