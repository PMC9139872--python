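import numpy as np
import pytest

from ulcerquant import RGBImage
from ulcerquant.synthetic import LesionSpec, make_gastric_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ethanol_fixture():
    """Noisy ethanol-phenotype image (red stripes on pink tissue) + truth."""
    spec = LesionSpec(
        phenotype="ethanol_stripe", area_fraction_target=0.05, seed=7
    )
    image, mask = make_gastric_image(spec)
    return spec, image, mask


@pytest.fixture
def clean_ethanol_fixture():
    """Noise-free ethanol image with a wide red gap to the background."""
    spec = LesionSpec(
        phenotype="ethanol_stripe",
        lesion_red=220,
        background_rgb=(120, 145, 150),
        area_fraction_target=0.05,
        noise_sd=0.0,
        seed=11,
    )
    image, mask = make_gastric_image(spec)
    return spec, image, mask


def random_image(rng, h=16, w=16):
    return RGBImage(rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8))
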