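import numpy as np
import pandas as pd
import pytest

from bessellight import blink_sim as bs
from bessellight.beam_optics import GaussianBeamSpec, OpticalConfig


@pytest.fixture
def cfg():
    return OpticalConfig()


@pytest.fixture
def gauss_spec():
    return GaussianBeamSpec(w=1.0)


@pytest.fixture
def psf():
    return bs.AstigmaticPSFModel()


@pytest.fixture
def cam():
    return bs.CameraModel(frame_shape=(48, 48))


@pytest.fixture
def random_spots_stack(psf, cam):
    """One 5000-photon emitter per frame at known positions, with noise."""
    rng = np.random.default_rng(7)
    n = 150
    truth = pd.DataFrame({
        "frame": np.arange(n),
        "emitter": 0,
        "x": rng.uniform(1000.0, 3800.0, n),
        "y": rng.uniform(1000.0, 3800.0, n),
        "z": rng.uniform(-350.0, 350.0, n),
        "photons": 5000.0,
    })
    stack = bs.render_frame_stack(truth, psf, cam, seed=11)
    return stack, truth
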