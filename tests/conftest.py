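import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from telotrack.models import AcquisitionConfig


@pytest.fixture
def acq_small():
    """Short movie for fast unit tests."""
    return AcquisitionConfig(n_frames=32, image_shape=(128, 128))


@pytest.fixture
def acq_default():
    """Full-scale acquisition: 480 frames, dt 0.25 s, 512x512, 66.3 nm px."""
    return AcquisitionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gapped_trajectory(rng, n_total, min_present=2):
    """Random walk with a random subset of frames observed."""
    from telotrack.models import Trajectory

    n_present = int(rng.integers(min_present, n_total + 1))
    frames = np.sort(rng.choice(n_total, size=n_present, replace=False))
    positions = np.cumsum(rng.normal(0, 50.0, size=(n_present, 2)), axis=0)
    return Trajectory(traj_id=0, frames=frames, positions=positions,
                      n_total_frames=n_total, dt=0.25)
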