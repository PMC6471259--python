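import numpy as np
import pytest

from mmhar.types import (
    BehaviorLabel,
    ImuStream,
    JointName,
    N_JOINTS,
    SensorSite,
    SkeletonFrame,
    SkeletonSequence,
    Trial,
)
from mmhar.synthetic import GeneratorConfig, generate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def make_frame(rng, t=0.0):
    """A random non-degenerate skeleton frame (upright-ish geometry)."""
    positions = rng.normal(0.0, 0.3, (N_JOINTS, 3))
    positions[int(JointName.HEAD)] = (0.0, 1.7, 0.0) + rng.normal(0, 0.05, 3)
    positions[int(JointName.SHOULDER_LEFT)] = (0.2, 1.4, 0.0) + rng.normal(0, 0.02, 3)
    positions[int(JointName.SHOULDER_RIGHT)] = (-0.2, 1.4, 0.0) + rng.normal(0, 0.02, 3)
    positions[int(JointName.FOOT_LEFT)] = (0.1, 0.0, 0.1) + rng.normal(0, 0.02, 3)
    positions[int(JointName.FOOT_RIGHT)] = (-0.1, 0.0, 0.1) + rng.normal(0, 0.02, 3)
    return SkeletonFrame(t=t, positions=positions)


def make_sequence(rng, n_frames=20, rate=30.0):
    times = np.arange(n_frames) / rate
    positions = np.stack([make_frame(rng, t).positions for t in times])
    return SkeletonSequence(times=times, positions=positions, rate_hz=rate)


def make_stream(rng, site=SensorSite.EL, n=50, rate=100.0):
    times = np.arange(n) / rate
    return ImuStream(
        site=site,
        times=times,
        gyro=rng.normal(0, 1, (n, 3)),
        accel=rng.normal(0, 1, (n, 3)),
        rate_hz=rate,
    )


def make_trial(rng, label=BehaviorLabel.BP, n_frames=20, n_samples=60):
    return Trial(
        trial_id="t0",
        user_id="u0",
        skeleton=make_sequence(rng, n_frames),
        imu={s: make_stream(rng, s, n_samples) for s in SensorSite},
        label=label,
    )


@pytest.fixture
def synthetic_trial():
    """One generated trial with its ground truth, default conditions."""
    return generate_trial(BehaviorLabel.DS, 1.62, GeneratorConfig(), seed=7)
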