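"""Activity segmentation by difference signals and a relative threshold.

Each modality yields a nonnegative per-step difference signal: the Euclidean
distance between consecutive skeleton centroids for the depth camera, and the
Euclidean norm of the consecutive-sample difference per 3-axis channel for
each IMU.  Steps whose difference exceeds 5 % of that signal's own maximum
are treated as movement; the per-sensor spans (first-above to last-above) are
fused across all nine sensors by taking the earliest start and the latest
end.  The threshold is relative, so the rule is invariant to positive
rescaling of any signal and to constant offsets in the raw streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .types import SkeletonFrame, SkeletonSequence, ImuStream, Trial, ValidationError

__all__ = [
    "SegmentationConfig",
    "DifferenceSeries",
    "Span",
    "FusedSegment",
    "NoActivityError",
    "compute_centroid",
    "centroid_difference_series",
    "imu_difference_series",
    "detect_span",
    "fuse_spans",
    "segment_trial",
    "resample_uniform",
]


class NoActivityError(RuntimeError):
    """No modality shows any movement in the trial."""


@dataclass(frozen=True)
class SegmentationConfig:
    threshold_fraction: float = 0.05
    resample_points: int = 60

    def __post_init__(self):
        if not 0 < self.threshold_fraction < 1:
            raise ValidationError("threshold_fraction must be in (0, 1)")
        if self.resample_points < 2:
            raise ValidationError("resample_points must be >= 2")


@dataclass
class DifferenceSeries:
    """Per-step difference magnitudes; value i spans samples i..i+1 and is
    stamped with the later sample's timestamp."""

    t: np.ndarray
    values: np.ndarray
    source: str

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape or self.t.ndim != 1:
            raise ValidationError("DifferenceSeries: t and values must be equal-length 1-D")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("DifferenceSeries: values must be nonnegative")


@dataclass(frozen=True)
class Span:
    t_start: float
    t_end: float
    source: str

    def __post_init__(self):
        if self.t_start > self.t_end:
            raise ValidationError("Span: t_start must be <= t_end")


@dataclass
class FusedSegment:
    """Active time span after cross-sensor fusion: earliest start, latest end."""

    t_start: float
    t_end: float
    contributing: List[Span] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def compute_centroid(frame: SkeletonFrame) -> np.ndarray:
    """Component-wise mean of the 25 joint positions."""
    return frame.positions.mean(axis=0)


def centroid_difference_series(seq: SkeletonSequence) -> DifferenceSeries:
    """Euclidean distance between consecutive frame centroids."""
    if len(seq) < 2:
        raise ValidationError("need at least 2 frames")
    centroids = seq.positions.mean(axis=1)
    d = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    return DifferenceSeries(t=seq.times[1:], values=d, source="depth")


def imu_difference_series(stream: ImuStream, channel: str) -> DifferenceSeries:
    """Euclidean norm of the consecutive-sample difference on one 3-axis channel."""
    if len(stream) < 2:
        raise ValidationError("need at least 2 samples")
    sig = stream.channel(channel)
    d = np.linalg.norm(np.diff(sig, axis=0), axis=1)
    return DifferenceSeries(t=stream.times[1:], values=d, source=f"{channel}@{stream.site.name}")


def detect_span(series: DifferenceSeries, config: SegmentationConfig = SegmentationConfig()) -> Optional[Span]:
    """First-above to last-above the relative threshold; None if the signal is flat.

    The threshold is ``threshold_fraction * max(values)`` and "above" is
    strict, so values tied at exactly the threshold are excluded.
    """
    if series.values.size == 0:
        raise ValidationError("empty difference series")
    peak = series.values.max()
    if peak <= 0:
        return None
    above = np.nonzero(series.values > config.threshold_fraction * peak)[0]
    # peak itself is strictly above any fraction < 1 of itself, so `above` is nonempty
    return Span(float(series.t[above[0]]), float(series.t[above[-1]]), series.source)


def fuse_spans(spans: Sequence[Span]) -> FusedSegment:
    """Earliest start and latest end over the per-sensor spans."""
    spans = [s for s in spans if s is not None]
    if not spans:
        raise NoActivityError("no activity detected in any modality")
    return FusedSegment(
        t_start=min(s.t_start for s in spans),
        t_end=max(s.t_end for s in spans),
        contributing=list(spans),
    )


def trial_difference_series(trial: Trial) -> List[DifferenceSeries]:
    """The nine per-sensor difference signals: 1 centroid + 4 gyro + 4 accel."""
    series = [centroid_difference_series(trial.skeleton)]
    for channel in ("gyro", "accel"):
        for site, stream in sorted(trial.imu.items()):
            series.append(imu_difference_series(stream, channel))
    return series


def segment_trial(trial: Trial, config: SegmentationConfig = SegmentationConfig()) -> FusedSegment:
    """Detect and fuse the active span across all nine sensors of a trial."""
    spans = [detect_span(s, config) for s in trial_difference_series(trial)]
    return fuse_spans([s for s in spans if s is not None])


def resample_uniform(times: np.ndarray, values: np.ndarray, n_points: int) -> Tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate a vector series onto n_points uniformly spaced
    timestamps spanning the input's time extent.

    ``values`` may have any trailing shape; interpolation is per component.
    The first and last output points equal the first and last inputs exactly.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if n_points < 2:
        raise ValidationError("n_points must be >= 2")
    if times.ndim != 1 or len(times) < 2:
        raise ValidationError("need at least 2 input points")
    if len(times) != len(values):
        raise ValidationError("times and values length mismatch")
    new_t = np.linspace(times[0], times[-1], n_points)
    flat = values.reshape(len(times), -1)
    out = np.empty((n_points, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(new_t, times, flat[:, j])
    # endpoints exact regardless of floating-point grid arithmetic
    out[0] = flat[0]
    out[-1] = flat[-1]
    return new_t, out.reshape((n_points,) + values.shape[1:])
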