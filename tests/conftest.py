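import numpy as np
import pytest

from azpunct.core import ImageChannel, SynapseMask
from azpunct.simgen import (
    GroundTruthPunctum,
    MaskSpec,
    SceneSpec,
    realize_mask,
    render_channel,
)


@pytest.fixture
def centered_mask_spec():
    return MaskSpec("rectangle", {"center_x_nm": 1280, "center_y_nm": 1280,
                                  "width_nm": 2400, "height_nm": 2400})


def make_single_punctum_scene(x_nm, y_nm, amplitude=150.0, fwhm_nm=100.0,
                              background=0.0, read_noise_sd=0.0,
                              size_px=128, channel="ch"):
    """One isolated Gaussian punctum in a size_px x size_px field, 20 nm px."""
    half = size_px * 20.0 / 2
    spec = MaskSpec("rectangle", {"center_x_nm": half, "center_y_nm": half,
                                  "width_nm": 2 * half - 160,
                                  "height_nm": 2 * half - 160})
    p = GroundTruthPunctum(0, channel, x_nm, y_nm, amplitude, fwhm_nm)
    return SceneSpec(size_px, size_px, 20.0, [channel], [p], spec,
                     background_level=background, read_noise_sd=read_noise_sd)


@pytest.fixture
def single_punctum_factory():
    return make_single_punctum_scene


@pytest.fixture
def rendered_punctum():
    """Noiseless isolated punctum (image, mask, scene) on a 128 px field."""
    scene = make_single_punctum_scene(1280.0, 1280.0)
    img = render_channel(scene, "ch")
    mask = realize_mask(scene.mask_spec, 128, 128, 20.0)
    return img, mask, scene


@pytest.fixture
def full_mask():
    return SynapseMask(pixels=np.ones((128, 128), dtype=bool), pixel_size_nm=20.0)


def image_of(array, pixel_size_nm=20.0, channel="ch"):
    return ImageChannel(pixels=np.asarray(array, dtype=float),
                        pixel_size_nm=pixel_size_nm, channel=channel)
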