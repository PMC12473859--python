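import numpy as np
import pytest

from gaitcomp.pose_io import N_KEYPOINTS, PoseSequence
from gaitcomp.synth_cohort import SynthCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests."""
    cfg = SynthCohortConfig(n_participants=8, n_frames=100, seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(417)


def make_sequence(xy, scores=None, frame_index=None, pid="T1", fps=30.0):
    """Build a PoseSequence from an (n, 17, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    n = xy.shape[0]
    if scores is None:
        scores = np.full((n, N_KEYPOINTS), 0.9)
    if frame_index is None:
        frame_index = np.arange(n)
    return PoseSequence(participant_id=pid, frame_index=frame_index,
                        xy=xy, scores=np.asarray(scores, float), fps=fps)


def random_sequence(rng, n_frames=20, pid="R1"):
    xy = rng.uniform(0, 700, size=(n_frames, N_KEYPOINTS, 2))
    scores = rng.uniform(0.31, 1.0, size=(n_frames, N_KEYPOINTS))
    return make_sequence(xy, scores, pid=pid)
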