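"""Synthetic multimodal behavior trials.

Generates labeled trials with the statistical structure the pipeline
assumes: one skeleton stream (30 Hz) and four IMU streams (100 Hz) per
trial, a single active movement window inside an otherwise idle recording,
class-dependent limb motion, and per-user body heights drawn in
1.29-1.80 m.  Ten hand-crafted motion templates mirror the behavior
vocabulary qualitatively: pitching is a fast right-arm arc, the bat swing a
two-arm planar arc, stretches and lunges are slow one-sided limb motions,
squatting is a vertical whole-body bob, walking is an anti-phase ankle
oscillation (with an asymmetric, slower variant for abnormal walking), and
coffee pouring is a small slow right-wrist rotation.

Active-phase signals are sinusoids with an integer number of cycles inside
the active window, so they enter and leave the window at zero value but
maximal slope — the per-step difference signal used by the segmenter rises
immediately at the true boundary.  Idle jitter (1 % of the active amplitude)
and sensor measurement noise are band-limited processes (Gaussian knots at
0.5 Hz, linearly interpolated): their per-step differences stay far below
the 5 %-of-maximum segmentation threshold, while their in-window amplitude
still perturbs the statistical features.  Accelerometers carry a constant
gravity offset.  Each frame's skeleton is rescaled about the foot midpoint
so the measured head-to-foot-midpoint distance equals the drawn user height
exactly (consistent bone lengths, as a tracking SDK would enforce).

No biomechanical realism is claimed: the generator reproduces only the
structure the pipeline consumes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as mio
from .classify import ModalityId
from .types import (
    BehaviorLabel,
    ImuStream,
    JointName,
    N_JOINTS,
    SensorSite,
    SkeletonSequence,
    Trial,
    ValidationError,
)

__all__ = [
    "GeneratorConfig",
    "MotionTemplate",
    "SyntheticDataset",
    "generate_trial",
    "generate_trials",
    "generate_dataset",
    "degrade_modality",
]

_REFERENCE_HEIGHT = 1.70  # template joint amplitudes are stated at this stature
_GRAVITY = np.array([0.0, 9.81, 0.0])
_KNOT_HZ = 0.5  # band limit of jitter / measurement noise
_JITTER_FRACTION = 0.01  # idle jitter sd as a fraction of active amplitude
_AMPFAC_SD = 0.04  # per-trial amplitude variability


@dataclass(frozen=True)
class GeneratorConfig:
    n_users: int = 10
    n_repetitions: int = 10
    behaviors: Tuple[BehaviorLabel, ...] = tuple(BehaviorLabel)
    height_range_m: Tuple[float, float] = (1.29, 1.80)
    skeleton_rate_hz: float = 30.0
    imu_rate_hz: float = 100.0
    trial_duration_s: float = 10.0
    active_window_s: Tuple[float, float] = (2.0, 6.0)
    noise_sd_per_modality: Dict[ModalityId, float] = field(
        default_factory=lambda: {
            ModalityId.DEPTH: 0.003,  # m, per joint
            ModalityId.GYRO: 0.02,
            ModalityId.ACCEL: 0.015,
        }
    )
    zero_signal: bool = False  # all templates muted; only noise remains
    seed: int = 0

    def __post_init__(self):
        if self.skeleton_rate_hz <= 0 or self.imu_rate_hz <= 0:
            raise ValidationError("sampling rates must be positive")
        lo, hi = self.height_range_m
        if not 0 < lo <= hi:
            raise ValidationError("height range must be positive and ordered")
        t0, t1 = self.active_window_s
        if not 0 <= t0 < t1 <= self.trial_duration_s:
            raise ValidationError("active window must lie inside the trial")

    @property
    def n_trials(self) -> int:
        return self.n_users * self.n_repetitions * len(self.behaviors)


# --------------------------------------------------------------------------
# base pose: a standing skeleton, y up, x to the subject's left, z forward;
# scaled so the head-to-foot-midpoint distance is exactly 1.
_RAW_POSE = {
    JointName.SPINE_BASE: (0.00, 0.95, 0.00),
    JointName.SPINE_MID: (0.00, 1.15, 0.00),
    JointName.NECK: (0.00, 1.38, 0.00),
    JointName.HEAD: (0.00, 1.55, 0.00),
    JointName.SHOULDER_LEFT: (0.20, 1.35, 0.00),
    JointName.ELBOW_LEFT: (0.25, 1.10, 0.00),
    JointName.WRIST_LEFT: (0.27, 0.88, 0.02),
    JointName.HAND_LEFT: (0.28, 0.80, 0.04),
    JointName.SHOULDER_RIGHT: (-0.20, 1.35, 0.00),
    JointName.ELBOW_RIGHT: (-0.25, 1.10, 0.00),
    JointName.WRIST_RIGHT: (-0.27, 0.88, 0.02),
    JointName.HAND_RIGHT: (-0.28, 0.80, 0.04),
    JointName.HIP_LEFT: (0.10, 0.90, 0.00),
    JointName.KNEE_LEFT: (0.11, 0.50, 0.02),
    JointName.ANKLE_LEFT: (0.11, 0.08, 0.02),
    JointName.FOOT_LEFT: (0.11, 0.02, 0.12),
    JointName.HIP_RIGHT: (-0.10, 0.90, 0.00),
    JointName.KNEE_RIGHT: (-0.11, 0.50, 0.02),
    JointName.ANKLE_RIGHT: (-0.11, 0.08, 0.02),
    JointName.FOOT_RIGHT: (-0.11, 0.02, 0.12),
    JointName.SPINE_SHOULDER: (0.00, 1.32, 0.00),
    JointName.HAND_TIP_LEFT: (0.285, 0.74, 0.05),
    JointName.THUMB_LEFT: (0.26, 0.78, 0.06),
    JointName.HAND_TIP_RIGHT: (-0.285, 0.74, 0.05),
    JointName.THUMB_RIGHT: (-0.26, 0.78, 0.06),
}


def _base_pose() -> np.ndarray:
    pose = np.zeros((N_JOINTS, 3))
    for j, p in _RAW_POSE.items():
        pose[int(j)] = p
    foot_mid = 0.5 * (pose[int(JointName.FOOT_LEFT)] + pose[int(JointName.FOOT_RIGHT)])
    h = np.linalg.norm(pose[int(JointName.HEAD)] - foot_mid)
    return pose / h


BASE_POSE = _base_pose()


@dataclass(frozen=True)
class MotionTemplate:
    """Parametric per-class motion: sinusoidal joint displacements, a
    whole-body translation, and per-site gyro/accel waveforms.

    Amplitudes: skeleton in meters at 1.70 m stature, gyro/accel in the
    sensor's native units; frequencies in Hz (rounded to an integer number
    of cycles inside the active window at generation time).  Opposite signs
    between left/right entries encode anti-phase motion.
    """

    behavior: BehaviorLabel
    joints: Dict[JointName, Tuple[Tuple[float, float, float], float]]
    translation: Tuple[Tuple[float, float, float], float]
    gyro: Dict[SensorSite, Tuple[Tuple[float, float, float], float]]
    accel: Dict[SensorSite, Tuple[Tuple[float, float, float], float]]


J = JointName
S = SensorSite

TEMPLATES: Dict[BehaviorLabel, MotionTemplate] = {
    BehaviorLabel.BP: MotionTemplate(  # baseball pitch: fast right-arm arc
        BehaviorLabel.BP,
        joints={
            J.ELBOW_RIGHT: ((-0.10, 0.15, 0.25), 2.5),
            J.WRIST_RIGHT: ((-0.15, 0.20, 0.35), 2.5),
            J.HAND_RIGHT: ((-0.15, 0.22, 0.38), 2.5),
            J.HAND_TIP_RIGHT: ((-0.16, 0.23, 0.40), 2.5),
            J.KNEE_LEFT: ((0.02, 0.03, 0.06), 2.5),
        },
        translation=((0.02, 0.03, 0.08), 1.0),
        gyro={
            S.ER: ((2.5, 1.8, 2.2), 2.5),
            S.EL: ((0.7, 0.5, 0.6), 2.5),
            S.AL: ((0.6, 0.45, 0.5), 1.5),
            S.AR: ((0.8, 0.5, 0.7), 1.5),
        },
        accel={
            S.ER: ((3.0, 2.5, 3.5), 2.5),
            S.EL: ((0.9, 0.7, 0.8), 2.5),
            S.AL: ((0.8, 0.6, 0.7), 1.5),
            S.AR: ((1.0, 0.7, 0.9), 1.5),
        },
    ),
    BehaviorLabel.BB: MotionTemplate(  # bat swing: two-arm horizontal arc
        BehaviorLabel.BB,
        joints={
            J.WRIST_LEFT: ((0.30, 0.05, 0.25), 2.0),
            J.WRIST_RIGHT: ((0.30, 0.05, 0.25), 2.0),
            J.HAND_LEFT: ((0.32, 0.06, 0.27), 2.0),
            J.HAND_RIGHT: ((0.32, 0.06, 0.27), 2.0),
            J.ELBOW_LEFT: ((0.15, 0.04, 0.12), 2.0),
            J.ELBOW_RIGHT: ((0.15, 0.04, 0.12), 2.0),
        },
        translation=((0.05, 0.02, 0.05), 2.0),
        gyro={
            S.EL: ((2.2, 1.0, 2.0), 2.0),
            S.ER: ((2.2, 1.0, 2.0), 2.0),
            S.AL: ((0.7, 0.5, 0.6), 2.0),
            S.AR: ((0.7, 0.5, 0.6), 2.0),
        },
        accel={
            S.EL: ((2.8, 1.2, 2.6), 2.0),
            S.ER: ((2.8, 1.2, 2.6), 2.0),
            S.AL: ((0.9, 0.7, 0.8), 2.0),
            S.AR: ((0.9, 0.7, 0.8), 2.0),
        },
    ),
    BehaviorLabel.LS: MotionTemplate(  # left stretch: slow left arm raise
        BehaviorLabel.LS,
        joints={
            J.WRIST_LEFT: ((0.10, 0.35, 0.05), 1.0),
            J.HAND_LEFT: ((0.10, 0.38, 0.05), 1.0),
            J.ELBOW_LEFT: ((0.06, 0.20, 0.03), 1.0),
        },
        translation=((0.02, 0.06, 0.02), 1.0),
        gyro={
            S.EL: ((1.8, 0.9, 0.8), 1.0),
            S.ER: ((0.6, 0.45, 0.5), 1.0),
            S.AL: ((0.6, 0.4, 0.45), 1.0),
            S.AR: ((0.6, 0.4, 0.45), 1.0),
        },
        accel={
            S.EL: ((2.2, 1.8, 0.9), 1.0),
            S.ER: ((0.8, 0.6, 0.7), 1.0),
            S.AL: ((0.7, 0.55, 0.6), 1.0),
            S.AR: ((0.7, 0.55, 0.6), 1.0),
        },
    ),
    BehaviorLabel.DS: MotionTemplate(  # deep squat: vertical whole-body bob
        BehaviorLabel.DS,
        joints={
            J.KNEE_LEFT: ((0.05, 0.10, 0.15), 1.0),
            J.KNEE_RIGHT: ((-0.05, 0.10, 0.15), 1.0),
            J.HIP_LEFT: ((0.02, 0.12, 0.05), 1.0),
            J.HIP_RIGHT: ((-0.02, 0.12, 0.05), 1.0),
        },
        translation=((0.02, 0.20, 0.05), 1.0),
        gyro={
            S.AL: ((1.6, 1.2, 1.0), 1.0),
            S.AR: ((1.6, 1.2, 1.0), 1.0),
            S.EL: ((0.8, 0.6, 0.7), 1.0),
            S.ER: ((0.8, 0.6, 0.7), 1.0),
        },
        accel={
            S.AL: ((2.5, 3.0, 1.5), 1.0),
            S.AR: ((2.5, 3.0, 1.5), 1.0),
            S.EL: ((1.2, 1.5, 0.8), 1.0),
            S.ER: ((1.2, 1.5, 0.8), 1.0),
        },
    ),
    BehaviorLabel.LL: MotionTemplate(  # left lunge: left leg forward drop
        BehaviorLabel.LL,
        joints={
            J.ANKLE_LEFT: ((0.05, 0.08, 0.30), 1.0),
            J.KNEE_LEFT: ((0.04, 0.10, 0.22), 1.0),
            J.HIP_LEFT: ((0.02, 0.08, 0.10), 1.0),
        },
        translation=((0.03, 0.12, 0.10), 1.0),
        gyro={
            S.AL: ((2.2, 1.5, 1.8), 1.0),
            S.AR: ((0.7, 0.5, 0.6), 1.0),
            S.EL: ((0.7, 0.5, 0.6), 1.0),
            S.ER: ((0.7, 0.5, 0.6), 1.0),
        },
        accel={
            S.AL: ((3.0, 2.2, 2.8), 1.0),
            S.AR: ((0.9, 0.7, 0.8), 1.0),
            S.EL: ((0.9, 0.8, 0.7), 1.0),
            S.ER: ((0.9, 0.8, 0.7), 1.0),
        },
    ),
    BehaviorLabel.NW: MotionTemplate(  # normal walking: anti-phase ankles
        BehaviorLabel.NW,
        joints={
            J.ANKLE_LEFT: ((0.02, 0.05, 0.22), 1.5),
            J.ANKLE_RIGHT: ((-0.02, -0.05, -0.22), 1.5),
            J.KNEE_LEFT: ((0.01, 0.04, 0.14), 1.5),
            J.KNEE_RIGHT: ((-0.01, -0.04, -0.14), 1.5),
            J.ELBOW_LEFT: ((0.01, 0.02, 0.08), 1.5),
            J.ELBOW_RIGHT: ((-0.01, -0.02, -0.08), 1.5),
        },
        translation=((0.01, 0.04, 0.03), 3.0),
        gyro={
            S.AL: ((1.8, 0.8, 1.5), 1.5),
            S.AR: ((-1.8, -0.8, -1.5), 1.5),
            S.EL: ((0.8, 0.45, 0.7), 1.5),
            S.ER: ((-0.8, -0.45, -0.7), 1.5),
        },
        accel={
            S.AL: ((2.2, 1.8, 2.4), 1.5),
            S.AR: ((-2.2, -1.8, -2.4), 1.5),
            S.EL: ((0.9, 0.6, 0.8), 1.5),
            S.ER: ((-0.9, -0.6, -0.8), 1.5),
        },
    ),
    BehaviorLabel.CP: MotionTemplate(  # coffee pour: small slow right wrist roll
        BehaviorLabel.CP,
        joints={
            J.WRIST_RIGHT: ((-0.08, 0.06, 0.10), 1.0),
            J.HAND_RIGHT: ((-0.10, 0.08, 0.12), 1.0),
            J.HAND_TIP_RIGHT: ((-0.11, 0.09, 0.13), 1.0),
            J.ELBOW_RIGHT: ((-0.05, 0.04, 0.06), 1.0),
        },
        translation=((0.015, 0.01, 0.04), 1.0),
        gyro={
            S.ER: ((1.5, 2.0, 0.9), 1.0),
            S.EL: ((0.5, 0.45, 0.45), 1.0),
            S.AL: ((0.5, 0.4, 0.45), 1.0),
            S.AR: ((0.5, 0.45, 0.4), 1.0),
        },
        accel={
            S.ER: ((2.0, 1.5, 1.8), 1.0),
            S.EL: ((0.7, 0.6, 0.65), 1.0),
            S.AL: ((0.65, 0.6, 0.6), 1.0),
            S.AR: ((0.65, 0.6, 0.6), 1.0),
        },
    ),
}


def _mirror(tpl: MotionTemplate, behavior: BehaviorLabel) -> MotionTemplate:
    """Left/right-mirrored template (x negated, L/R joints and sites swapped)."""
    swap_j = {}
    for j, (amp, f) in tpl.joints.items():
        name = j.name
        if "LEFT" in name:
            other = JointName[name.replace("LEFT", "RIGHT")]
        elif "RIGHT" in name:
            other = JointName[name.replace("RIGHT", "LEFT")]
        else:
            other = j
        swap_j[other] = ((-amp[0], amp[1], amp[2]), f)
    swap_site = {S.EL: S.ER, S.ER: S.EL, S.AL: S.AR, S.AR: S.AL}
    return MotionTemplate(
        behavior,
        joints=swap_j,
        translation=((-tpl.translation[0][0],) + tuple(tpl.translation[0][1:]), tpl.translation[1]),
        gyro={swap_site[s]: v for s, v in tpl.gyro.items()},
        accel={swap_site[s]: v for s, v in tpl.accel.items()},
    )


def _asymmetric_walk() -> MotionTemplate:
    """Abnormal walking: the normal gait with a limp (left side amplified,
    right side damped) at a slower cadence."""
    nw = TEMPLATES[BehaviorLabel.NW]

    def scale(amp: Tuple[float, float, float], factor: float):
        return tuple(a * factor for a in amp)

    joints = {}
    for j, (amp, f) in nw.joints.items():
        factor = 1.4 if "LEFT" in j.name else 0.55
        joints[j] = (scale(amp, factor), 1.2)
    gyro = {
        s: (scale(amp, 1.4 if s in (S.EL, S.AL) else 0.55), 1.2) for s, (amp, _) in nw.gyro.items()
    }
    accel = {
        s: (scale(amp, 1.4 if s in (S.EL, S.AL) else 0.55), 1.2)
        for s, (amp, _) in nw.accel.items()
    }
    return MotionTemplate(
        BehaviorLabel.AW,
        joints=joints,
        translation=(scale(nw.translation[0], 1.1), 2.4),
        gyro=gyro,
        accel=accel,
    )


TEMPLATES[BehaviorLabel.RS] = _mirror(TEMPLATES[BehaviorLabel.LS], BehaviorLabel.RS)
TEMPLATES[BehaviorLabel.RL] = _mirror(TEMPLATES[BehaviorLabel.LL], BehaviorLabel.RL)
TEMPLATES[BehaviorLabel.AW] = _asymmetric_walk()


# --------------------------------------------------------------------------


def _active_signal(times, t0, t1, amp, freq_hz) -> np.ndarray:
    """Boxcar-windowed sinusoid with an integer cycle count in [t0, t1]."""
    amp = np.asarray(amp, dtype=float)
    window = t1 - t0
    cycles = max(1, int(round(freq_hz * window)))
    out = np.zeros((len(times), 3))
    mask = (times >= t0) & (times <= t1)
    tau = (times[mask] - t0) / window
    out[mask] = np.outer(np.sin(2.0 * np.pi * cycles * tau), amp)
    return out


def _smooth_noise(rng, times, sd, n_axes=3, knot_hz=_KNOT_HZ) -> np.ndarray:
    """Band-limited Gaussian noise: knots at knot_hz, linearly interpolated."""
    if sd <= 0:
        return np.zeros((len(times), n_axes))
    span = times[-1] - times[0]
    n_knots = max(2, int(np.ceil(span * knot_hz)) + 1)
    kt = np.linspace(times[0], times[-1], n_knots)
    kv = rng.normal(0.0, sd, (n_knots, n_axes))
    return np.column_stack([np.interp(times, kt, kv[:, a]) for a in range(n_axes)])


def _max_amp(entries) -> float:
    return max(float(np.linalg.norm(amp)) for amp, _ in entries) if entries else 0.0


def generate_trial(
    behavior: BehaviorLabel,
    user_height: float,
    config: GeneratorConfig = GeneratorConfig(),
    seed: int = 0,
    trial_id: str = "trial",
    user_id: str = "user",
) -> Tuple[Trial, dict]:
    """One synthetic trial plus its ground truth (label, activity window)."""
    lo, hi = config.height_range_m
    if not lo <= user_height <= hi:
        raise ValidationError(f"user height {user_height} outside configured range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    tpl = TEMPLATES[BehaviorLabel(behavior)]
    t0, t1 = config.active_window_s
    mute = 0.0 if config.zero_signal else 1.0
    ampfac = mute * float(np.clip(1.0 + _AMPFAC_SD * rng.standard_normal(), 0.85, 1.15))

    # ---- skeleton ----
    n_frames = int(round(config.trial_duration_s * config.skeleton_rate_hz)) + 1
    st = np.arange(n_frames) / config.skeleton_rate_hz
    scale = user_height / _REFERENCE_HEIGHT
    pos = user_height * BASE_POSE[None, :, :].repeat(n_frames, axis=0)
    for j, (amp, f) in tpl.joints.items():
        pos[:, int(j), :] += scale * ampfac * _active_signal(st, t0, t1, amp, f)
    tr_amp, tr_f = tpl.translation
    pos += (scale * ampfac * _active_signal(st, t0, t1, tr_amp, tr_f))[:, None, :]
    # idle whole-body jitter + per-joint measurement noise
    joint_amp = scale * max(_max_amp(list(tpl.joints.values())), float(np.linalg.norm(tr_amp)))
    pos += _smooth_noise(rng, st, ampfac * _JITTER_FRACTION * joint_amp)[:, None, :]
    depth_sd = config.noise_sd_per_modality.get(ModalityId.DEPTH, 0.0)
    pos += _smooth_noise(rng, st, depth_sd, n_axes=3 * N_JOINTS).reshape(n_frames, N_JOINTS, 3)
    # consistent bone lengths: rescale each frame so measured height == drawn height
    fl, fr, hd = int(JointName.FOOT_LEFT), int(JointName.FOOT_RIGHT), int(JointName.HEAD)
    foot_mid = 0.5 * (pos[:, fl] + pos[:, fr])
    h_meas = np.linalg.norm(pos[:, hd] - foot_mid, axis=1)
    pos = foot_mid[:, None, :] + (pos - foot_mid[:, None, :]) * (user_height / h_meas)[:, None, None]
    skeleton = SkeletonSequence(times=st, positions=pos, rate_hz=config.skeleton_rate_hz)

    # ---- IMU ----
    n_samp = int(round(config.trial_duration_s * config.imu_rate_hz)) + 1
    it = np.arange(n_samp) / config.imu_rate_hz
    gyro_sd = config.noise_sd_per_modality.get(ModalityId.GYRO, 0.0)
    accel_sd = config.noise_sd_per_modality.get(ModalityId.ACCEL, 0.0)
    gyro_jit = ampfac * _JITTER_FRACTION * _max_amp(list(tpl.gyro.values()))
    accel_jit = ampfac * _JITTER_FRACTION * _max_amp(list(tpl.accel.values()))
    imu = {}
    for site in SensorSite:
        g_amp, g_f = tpl.gyro[site]
        a_amp, a_f = tpl.accel[site]
        g = (
            ampfac * _active_signal(it, t0, t1, g_amp, g_f)
            + _smooth_noise(rng, it, gyro_jit)
            + _smooth_noise(rng, it, gyro_sd)
        )
        a = (
            ampfac * _active_signal(it, t0, t1, a_amp, a_f)
            + _smooth_noise(rng, it, accel_jit)
            + _smooth_noise(rng, it, accel_sd)
            + _GRAVITY
        )
        imu[site] = ImuStream(site=site, times=it, gyro=g, accel=a, rate_hz=config.imu_rate_hz)

    trial = Trial(
        trial_id=trial_id,
        user_id=user_id,
        skeleton=skeleton,
        imu=imu,
        label=BehaviorLabel(behavior),
    )
    truth = {"label": BehaviorLabel(behavior), "active_window": (t0, t1), "height": user_height}
    return trial, truth


@dataclass
class SyntheticDataset:
    trials: List[Trial]
    truths: List[dict]
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.trials)


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def generate_trials(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """n_users x n_repetitions x |behaviors| labeled trials, in memory."""
    height_rng = np.random.default_rng(_child_seed(config.seed, 104729))
    lo, hi = config.height_range_m
    heights = height_rng.uniform(lo, hi, config.n_users)
    trials, truths = [], []
    index = 0
    for behavior in config.behaviors:
        for user in range(config.n_users):
            for rep in range(config.n_repetitions):
                trial, truth = generate_trial(
                    behavior,
                    float(heights[user]),
                    config,
                    seed=_child_seed(config.seed, 1, index),
                    trial_id=f"{BehaviorLabel(behavior).name}_u{user:02d}_r{rep:02d}",
                    user_id=f"u{user:02d}",
                )
                trials.append(trial)
                truths.append(truth)
                index += 1
    return SyntheticDataset(trials=trials, truths=truths, config=config)


def generate_dataset(config: GeneratorConfig, out_dir) -> Path:
    """Generate, write all trial files and a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset = generate_trials(config)
    records = []
    for trial, truth in zip(dataset.trials, dataset.truths):
        paths = mio.write_trial(trial, out_dir / "trials")
        rec = {
            "trial_id": trial.trial_id,
            "user_id": trial.user_id,
            "label": trial.label.name,
            "skeleton": str(paths["skeleton"].relative_to(out_dir)),
            "imu": {
                site.name: str(paths[f"imu_{site.name}"].relative_to(out_dir))
                for site in SensorSite
            },
            "active_window": list(truth["active_window"]),
        }
        records.append(rec)
    return mio.write_manifest(records, out_dir / "manifest.jsonl")


def degrade_modality(
    dataset: SyntheticDataset,
    modality: ModalityId,
    extra_noise_sd: float,
    seed: int = 0,
) -> SyntheticDataset:
    """Copy of the dataset with white Gaussian noise added to one modality.

    Labels and the other modalities are untouched.  White noise is used (not
    the generator's band-limited noise) so repeated applications add in
    variance: degrading with sd a then sd b matches a single sqrt(a^2+b^2)
    degradation in distribution.
    """
    if modality not in tuple(ModalityId):
        raise ValidationError(f"unknown modality {modality!r}")
    if extra_noise_sd < 0:
        raise ValidationError("extra_noise_sd must be >= 0")
    if extra_noise_sd == 0:
        return dataset
    rng = np.random.default_rng(_child_seed(seed, 2))
    trials = []
    for trial in dataset.trials:
        t = copy.deepcopy(trial)
        if modality == ModalityId.DEPTH:
            t.skeleton.positions = t.skeleton.positions + rng.normal(
                0.0, extra_noise_sd, t.skeleton.positions.shape
            )
        else:
            attr = "gyro" if modality == ModalityId.GYRO else "accel"
            for site in SensorSite:
                stream = t.imu[site]
                setattr(
                    stream,
                    attr,
                    getattr(stream, attr) + rng.normal(0.0, extra_noise_sd, (len(stream), 3)),
                )
        trials.append(t)
    return SyntheticDataset(trials=trials, truths=dataset.truths, config=dataset.config)
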