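import numpy as np
import pytest

from bellkin import correction, synthetic
from bellkin.types import HalfProfile


def half(points, time=0.0, side="right", frame_index=None):
    return HalfProfile(time=time, side=side, points=np.asarray(points, float), frame_index=frame_index)


@pytest.fixture(scope="session")
def clean_scene():
    """Two swimming cycles through an identity camera, no noise."""
    return synthetic.make_scene(camera=synthetic.CameraSpec(), n_cycles=2, seed=0)


@pytest.fixture(scope="session")
def clean_corrected(clean_scene):
    halves, scales, body_frames = correction.correct_sequence(
        clean_scene.frames, clean_scene.config
    )
    return halves, scales, body_frames


@pytest.fixture(scope="session")
def corrupted_scene():
    """Zoom 1.3x, 2%/cycle linear drift, +-7 deg roll, noiseless."""
    spec = synthetic.SwimmerSpec()
    cam = synthetic.CameraSpec(
        zoom_total=1.3,
        drift_rate=0.02 / spec.period,
        roll_amplitude_deg=7.0,
        roll_period_s=2.0 * spec.period,
        noise_sd=0.0,
    )
    return synthetic.make_scene(spec=spec, camera=cam, n_cycles=2, seed=0)


@pytest.fixture(scope="session")
def corrupted_corrected(corrupted_scene):
    halves, scales, body_frames = correction.correct_sequence(
        corrupted_scene.frames, corrupted_scene.config
    )
    return halves, scales, body_frames
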