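import numpy as np
import pytest

from skelwin.preprocess import VideoPoseTrack
from skelwin.skeleton_io import FEATURES_PER_SKELETON
from skelwin.synthetic import confusable_pair_config, simulate_tracks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_track(rng, n_frames, fps=18, labels=None, video_id="t"):
    """Random track: iid features, optional explicit labels."""
    if labels is None:
        labels = rng.integers(1, 13, size=n_frames)
    return VideoPoseTrack(
        video_id=video_id,
        fps=fps,
        frame_indices=np.arange(n_frames),
        features=rng.normal(size=(n_frames, FEATURES_PER_SKELETON)),
        labels=np.asarray(labels, dtype=int),
    )


@pytest.fixture(scope="session")
def confusable_tracks():
    """The fall vs lie-down study dataset (fixed seed, ~200 2-s windows)."""
    return simulate_tracks(confusable_pair_config(seed=1))
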