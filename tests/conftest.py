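import numpy as np
import pytest

from standmap.metrics import ResampledSequence
from standmap.object_frame import SkeletonSequence


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation via QR with sign fixing."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def random_sequence(rng) -> SkeletonSequence:
    """A smooth random camera-frame sequence of 40 frames."""
    base = rng.normal(size=(1, 13, 3))
    drift = np.linspace(0, 1, 40)[:, None, None] * rng.normal(size=(1, 13, 3))
    return SkeletonSequence(trial_id="rand", frames=base + drift)


def random_resampled(rng, trial_id: str, n_frames: int = 500) -> ResampledSequence:
    return ResampledSequence(trial_id=trial_id, frames=rng.normal(size=(n_frames, 13, 3)))
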