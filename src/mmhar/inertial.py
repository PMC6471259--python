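"""Windowed statistical features for the inertial modalities.

The fused segment is split into M equal-duration windows (M = 6 by default).
Per window, per sensor, per axis, the features are the arithmetic mean, the
population standard deviation, and the variance of the raw in-window samples
of the selected channel (gyro or accel).  Stacking the four sensors in the
fixed site order EL, ER, AL, AR gives an M x 4 x 9 array per channel, with
the 9 statistics ordered (mu_x, mu_y, mu_z, sd_x, sd_y, sd_z, var_x, var_y,
var_z).  The variance entries are the exact squares of the std entries; the
redundancy is kept deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .segmentation import FusedSegment
from .types import ImuStream, SITE_ORDER, Trial, ValidationError

__all__ = [
    "WindowingConfig",
    "InertialFeatureMatrix",
    "window_bounds",
    "windowed_stats",
    "inertial_features",
    "flatten_inertial",
    "unflatten_inertial",
    "concat_inertial",
]

N_STATS = 9


class EmptyWindowError(ValidationError):
    """The first window of a segment contains no samples."""


@dataclass(frozen=True)
class WindowingConfig:
    M: int = 6

    def __post_init__(self):
        if self.M < 1:
            raise ValidationError("M must be >= 1")


@dataclass
class InertialFeatureMatrix:
    """M x 4 x 9 statistics for one channel across the four sensors."""

    channel: str  # "gyro" | "accel"
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (4, N_STATS):
            raise ValidationError(f"expected (M, 4, 9) array, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite feature values")


def window_bounds(segment: FusedSegment, M: int) -> List[Tuple[float, float]]:
    """M equal contiguous [lo, hi) intervals covering the segment (last closed)."""
    if M < 1:
        raise ValidationError("M must be >= 1")
    if segment.duration <= 0:
        raise ValidationError("segment duration must be positive")
    edges = np.linspace(segment.t_start, segment.t_end, M + 1)
    return [(float(edges[w]), float(edges[w + 1])) for w in range(M)]


def windowed_stats(
    stream: ImuStream,
    channel: str,
    segment: FusedSegment,
    config: WindowingConfig = WindowingConfig(),
) -> np.ndarray:
    """M x 9 (mean, population std, variance per axis) for one sensor/channel.

    A window with no samples inherits the previous window's statistics
    (possible only at unrealistically low sampling rates); an empty first
    window is an error.
    """
    sig = stream.channel(channel)
    bounds = window_bounds(segment, config.M)
    out = np.empty((config.M, N_STATS))
    for w, (lo, hi) in enumerate(bounds):
        if w == config.M - 1:
            mask = (stream.times >= lo) & (stream.times <= hi)
        else:
            mask = (stream.times >= lo) & (stream.times < hi)
        if not mask.any():
            if w == 0:
                raise EmptyWindowError(
                    f"no {channel}@{stream.site.name} samples in the first window"
                )
            out[w] = out[w - 1]
            continue
        x = sig[mask]
        mu = x.mean(axis=0)
        sd = x.std(axis=0)  # population convention (divide by n)
        out[w] = np.concatenate([mu, sd, sd**2])
    return out


def inertial_features(
    trial: Trial,
    segment: FusedSegment,
    config: WindowingConfig = WindowingConfig(),
) -> Tuple[InertialFeatureMatrix, InertialFeatureMatrix]:
    """(gyro, accel) M x 4 x 9 matrices, sensors stacked in EL, ER, AL, AR order."""
    out = []
    for channel in ("gyro", "accel"):
        stack = np.stack(
            [windowed_stats(trial.imu[site], channel, segment, config) for site in SITE_ORDER],
            axis=1,
        )
        out.append(InertialFeatureMatrix(channel=channel, values=stack))
    return out[0], out[1]


def flatten_inertial(matrix: InertialFeatureMatrix) -> np.ndarray:
    """M x 36 sequence: per window, the 4 sensors' 9 statistics in site order."""
    m = matrix.values
    return m.reshape(m.shape[0], 4 * N_STATS)


def unflatten_inertial(flat: np.ndarray, channel: str = "gyro") -> InertialFeatureMatrix:
    """Inverse of :func:`flatten_inertial`."""
    flat = np.asarray(flat, dtype=float)
    return InertialFeatureMatrix(channel=channel, values=flat.reshape(flat.shape[0], 4, N_STATS))


def concat_inertial(matrix: InertialFeatureMatrix) -> np.ndarray:
    """Single 36*M vector (window-major), the flat input used by the SVM baseline."""
    return flatten_inertial(matrix).reshape(-1)
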