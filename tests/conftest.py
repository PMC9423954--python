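import numpy as np
import pytest

from acupilot import synth


@pytest.fixture(scope="session")
def hand_model():
    return synth.generate_hand_model(seed=0)


@pytest.fixture(scope="session")
def clean_scene(hand_model):
    """A noiseless, mildly rotated scene with its exact detections."""
    scene, detections = synth.generate_scene(
        hand_model, yaw_deg=12.0, tilt_x_deg=3.0, tilt_y_deg=-2.0, seed=1
    )
    return scene, detections


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
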