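"""Domain data model for multimodal behavior trials.

A trial couples one depth-camera skeleton stream (25 named joints per frame,
meters) with four body-worn IMU streams (3-axis gyroscope + 3-axis
accelerometer, one sensor per elbow and ankle).  Timestamps are seconds
relative to trial start; the modalities have independent native sampling
rates and need not share sample instants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "JointName",
    "SensorSite",
    "BehaviorLabel",
    "SkeletonFrame",
    "SkeletonSequence",
    "ImuSample",
    "ImuStream",
    "Trial",
    "ValidationError",
    "N_JOINTS",
]

N_JOINTS = 25


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class JointName(enum.IntEnum):
    """The 25 skeleton joints of the Kinect-V2 SDK, in SDK index order."""

    SPINE_BASE = 0
    SPINE_MID = 1
    NECK = 2
    HEAD = 3
    SHOULDER_LEFT = 4
    ELBOW_LEFT = 5
    WRIST_LEFT = 6
    HAND_LEFT = 7
    SHOULDER_RIGHT = 8
    ELBOW_RIGHT = 9
    WRIST_RIGHT = 10
    HAND_RIGHT = 11
    HIP_LEFT = 12
    KNEE_LEFT = 13
    ANKLE_LEFT = 14
    FOOT_LEFT = 15
    HIP_RIGHT = 16
    KNEE_RIGHT = 17
    ANKLE_RIGHT = 18
    FOOT_RIGHT = 19
    SPINE_SHOULDER = 20
    HAND_TIP_LEFT = 21
    THUMB_LEFT = 22
    HAND_TIP_RIGHT = 23
    THUMB_RIGHT = 24


class SensorSite(enum.IntEnum):
    """Wearable sensor placements: left/right elbow, left/right ankle."""

    EL = 0
    ER = 1
    AL = 2
    AR = 3

    @property
    def k(self) -> int:
        """1-based sensor index k = 1..4."""
        return int(self) + 1


#: Fixed site order used whenever the four sensors are stacked.
SITE_ORDER = (SensorSite.EL, SensorSite.ER, SensorSite.AL, SensorSite.AR)


class BehaviorLabel(enum.IntEnum):
    """The 10-behavior vocabulary (on-field, warm-up and daily activities)."""

    BP = 0  # baseball pitch
    BB = 1  # baseball bat swing
    LS = 2  # left stretch
    RS = 3  # right stretch
    DS = 4  # deep squat
    LL = 5  # left lunge
    RL = 6  # right lunge
    NW = 7  # normal walking
    AW = 8  # abnormal walking
    CP = 9  # coffee pouring


def _as_float_array(x, shape, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise ValidationError(f"{name}: expected shape {shape}, got {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{name}: contains non-finite values")
    return a


@dataclass(frozen=True)
class SkeletonFrame:
    """One skeleton sample: timestamp + 25 joint positions (meters)."""

    t: float
    positions: np.ndarray  # (25, 3), row order = JointName index

    def __post_init__(self):
        object.__setattr__(
            self, "positions", _as_float_array(self.positions, (N_JOINTS, 3), "positions")
        )

    def joint(self, name: JointName) -> np.ndarray:
        return self.positions[int(name)]


def _check_times(t: np.ndarray, what: str) -> None:
    if t.ndim != 1 or len(t) < 2:
        raise ValidationError(f"{what}: need at least 2 samples, got {t.size}")
    if not np.all(np.isfinite(t)):
        raise ValidationError(f"{what}: non-finite timestamps")
    if not np.all(np.diff(t) > 0):
        raise ValidationError(f"{what}: timestamps must be strictly increasing")


@dataclass
class SkeletonSequence:
    """Time-ordered skeleton frames stored as dense arrays."""

    times: np.ndarray  # (T,)
    positions: np.ndarray  # (T, 25, 3)
    rate_hz: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        _check_times(self.times, "SkeletonSequence")
        self.positions = _as_float_array(
            self.positions, (len(self.times), N_JOINTS, 3), "SkeletonSequence.positions"
        )
        if self.rate_hz <= 0:
            raise ValidationError("SkeletonSequence: rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(float(self.times[i]), self.positions[i])

    @property
    def frames(self):
        return [self.frame(i) for i in range(len(self))]


@dataclass(frozen=True)
class ImuSample:
    """One IMU sample: timestamp + 3-axis angular rate + 3-axis acceleration."""

    t: float
    gyro: np.ndarray  # (3,)
    accel: np.ndarray  # (3,)

    def __post_init__(self):
        object.__setattr__(self, "gyro", _as_float_array(self.gyro, (3,), "gyro"))
        object.__setattr__(self, "accel", _as_float_array(self.accel, (3,), "accel"))


@dataclass
class ImuStream:
    """Time-ordered gyro+accel samples for one body-worn sensor."""

    site: SensorSite
    times: np.ndarray  # (n,)
    gyro: np.ndarray  # (n, 3)
    accel: np.ndarray  # (n, 3)
    rate_hz: float

    def __post_init__(self):
        self.site = SensorSite(self.site)
        self.times = np.asarray(self.times, dtype=float)
        _check_times(self.times, f"ImuStream[{self.site.name}]")
        n = len(self.times)
        self.gyro = _as_float_array(self.gyro, (n, 3), "ImuStream.gyro")
        self.accel = _as_float_array(self.accel, (n, 3), "ImuStream.accel")
        if self.rate_hz <= 0:
            raise ValidationError("ImuStream: rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.times)

    def sample(self, i: int) -> ImuSample:
        return ImuSample(float(self.times[i]), self.gyro[i], self.accel[i])

    def channel(self, channel: str) -> np.ndarray:
        if channel == "gyro":
            return self.gyro
        if channel == "accel":
            return self.accel
        raise ValidationError(f"unknown IMU channel {channel!r}")


@dataclass
class Trial:
    """One recorded execution of one behavior by one user, all modalities."""

    trial_id: str
    user_id: str
    skeleton: SkeletonSequence
    imu: Mapping[SensorSite, ImuStream]
    label: Optional[BehaviorLabel] = None

    def __post_init__(self):
        missing = [s for s in SensorSite if s not in self.imu]
        if missing:
            raise ValidationError(
                f"Trial {self.trial_id}: missing sensor sites {[s.name for s in missing]}"
            )
        for site, stream in self.imu.items():
            if stream.site != site:
                raise ValidationError(
                    f"Trial {self.trial_id}: stream filed under {site.name} "
                    f"reports site {stream.site.name}"
                )
        # modality time ranges must overlap
        starts = [self.skeleton.times[0]] + [s.times[0] for s in self.imu.values()]
        ends = [self.skeleton.times[-1]] + [s.times[-1] for s in self.imu.values()]
        if max(starts) >= min(ends):
            raise ValidationError(f"Trial {self.trial_id}: modality time ranges do not overlap")
        if self.label is not None:
            self.label = BehaviorLabel(self.label)


def trials_equal(a: Trial, b: Trial, rtol: float = 0.0, atol: float = 1e-9) -> bool:
    """Value equality of two trials up to a numeric tolerance (IO round-trips)."""
    if (a.trial_id, a.user_id, a.label) != (b.trial_id, b.user_id, b.label):
        return False
    ok = np.allclose(a.skeleton.times, b.skeleton.times, rtol=rtol, atol=atol) and np.allclose(
        a.skeleton.positions, b.skeleton.positions, rtol=rtol, atol=atol
    )
    for site in SensorSite:
        sa, sb = a.imu[site], b.imu[site]
        ok = (
            ok
            and len(sa) == len(sb)
            and np.allclose(sa.times, sb.times, rtol=rtol, atol=atol)
            and np.allclose(sa.gyro, sb.gyro, rtol=rtol, atol=atol)
            and np.allclose(sa.accel, sb.accel, rtol=rtol, atol=atol)
        )
    return bool(ok)
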