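import numpy as np
import pytest

from rhdtyper.simulate import FieldGeometry, NoiseModel
from rhdtyper.types import Frame, Modality


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_geometry():
    """Default field but only the frames the pipeline actually consumes."""
    return FieldGeometry(n_bright_field_frames=2, n_fluorescence_frames=1)


@pytest.fixture
def noise():
    return NoiseModel()


def make_fluo_frame(pixels, pitch=0.16):
    return Frame(np.asarray(pixels), Modality.FLUORESCENCE, pitch)


def make_bf_frame(pixels, pitch=0.16):
    return Frame(np.asarray(pixels), Modality.BRIGHT_FIELD, pitch)


@pytest.fixture
def blank_fluo(noise, rng):
    img = np.clip(
        np.round(rng.normal(noise.background_mean, noise.background_sd, (256, 256))),
        0,
        65535,
    ).astype(np.uint16)
    return make_fluo_frame(img)
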