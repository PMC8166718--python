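import numpy as np
import pytest

from lumenseg.synthetic_data import SyntheticSceneParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_scene_params(**overrides):
    """16x16 scene small enough for fast unit tests."""
    defaults = dict(frame_size=(16, 16), n_frames=6, lumen_radii=(4.0, 3.0),
                    trajectory_amplitude=0.08, noise_sigma=0.01)
    defaults.update(overrides)
    return SyntheticSceneParams(**defaults)


@pytest.fixture
def tiny_dataset():
    """Three-video, two-patient 16x16 dataset for pipeline tests."""
    return generate_dataset(n_videos=3, frames_per_video=6,
                            params=tiny_scene_params(), seed=7,
                            patient_layout=("PA", "PA", "PB"))
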