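"""Time-variant skeleton-vector-projection features.

Per frame, joint positions are made user- and pose-relative in three steps:

1. normalize: subtract the SHOULDER_RIGHT position and divide by the body
   height h_t (distance from HEAD to the FOOT_LEFT/FOOT_RIGHT midpoint);
2. build a body-attached basis: shoulder vector S (SHOULDER_RIGHT ->
   SHOULDER_LEFT), foot vector F (SHOULDER_RIGHT -> foot midpoint), and
   their cross product N = S x F, each unit-normalized;
3. project every normalized joint onto (N, F, S) by inner products.

The result is a 25x3 slice per frame; stacking T resampled frames gives the
T x 25 x 3 spatio-temporal feature cube.  With the unit basis the features
are invariant to global translation, rotation, and uniform scaling of the
skeleton, so users of different heights map to the same representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import FusedSegment, resample_uniform
from .types import JointName, N_JOINTS, SkeletonFrame, SkeletonSequence, ValidationError

__all__ = [
    "DegenerateSkeletonError",
    "BodyBasis",
    "body_height",
    "normalize_joints",
    "body_basis",
    "frame_feature",
    "feature_cube",
    "flatten_skeleton",
    "unflatten_skeleton",
    "concat_skeleton",
]

_HEIGHT_GUARD = 1e-6
_BASIS_GUARD = 1e-9

_HEAD = int(JointName.HEAD)
_SL = int(JointName.SHOULDER_LEFT)
_SR = int(JointName.SHOULDER_RIGHT)
_FL = int(JointName.FOOT_LEFT)
_FR = int(JointName.FOOT_RIGHT)


class DegenerateSkeletonError(ValidationError):
    """Skeleton has (near-)zero height or a collapsed shoulder/foot geometry."""


@dataclass(frozen=True)
class BodyBasis:
    """Unit body-frame basis: normal N, shoulder S, foot F."""

    S: np.ndarray
    F: np.ndarray
    N: np.ndarray


def _heights(positions: np.ndarray) -> np.ndarray:
    """Body height per frame for a (..., 25, 3) position array."""
    foot_mid = 0.5 * (positions[..., _FL, :] + positions[..., _FR, :])
    return np.linalg.norm(positions[..., _HEAD, :] - foot_mid, axis=-1)


def body_height(frame: SkeletonFrame) -> float:
    """Distance from HEAD to the midpoint of the two FOOT joints (meters)."""
    h = float(_heights(frame.positions))
    if h < _HEIGHT_GUARD:
        raise DegenerateSkeletonError(f"body height {h:g} below guard {_HEIGHT_GUARD:g}")
    return h


def normalize_joints(frame: SkeletonFrame) -> np.ndarray:
    """Joint positions relative to SHOULDER_RIGHT, divided by body height."""
    h = body_height(frame)
    return (frame.positions - frame.positions[_SR]) / h


def _basis_arrays(positions: np.ndarray, unit: bool = True):
    """Vectorized basis construction for a (..., 25, 3) position array."""
    S = positions[..., _SL, :] - positions[..., _SR, :]
    foot_mid = 0.5 * (positions[..., _FL, :] + positions[..., _FR, :])
    F = foot_mid - positions[..., _SR, :]
    N = np.cross(S, F)
    n_norm = np.linalg.norm(N, axis=-1)
    if np.any(n_norm < _BASIS_GUARD):
        raise DegenerateSkeletonError("shoulder and foot vectors are parallel or zero")
    if unit:
        S = S / np.linalg.norm(S, axis=-1, keepdims=True)
        F = F / np.linalg.norm(F, axis=-1, keepdims=True)
        N = N / n_norm[..., None]
    return S, F, N


def body_basis(frame: SkeletonFrame, unit: bool = True) -> BodyBasis:
    """Body-attached basis (S, F, N = S x F) for one frame."""
    S, F, N = _basis_arrays(frame.positions, unit=unit)
    return BodyBasis(S=S, F=F, N=N)


def _frame_features(positions: np.ndarray, unit_basis: bool = True) -> np.ndarray:
    """Projection features for a (..., 25, 3) position array -> (..., 25, 3),
    last axis ordered (N, F, S)."""
    h = _heights(positions)
    if np.any(h < _HEIGHT_GUARD):
        raise DegenerateSkeletonError("body height below guard")
    rel = (positions - positions[..., _SR : _SR + 1, :]) / h[..., None, None]
    S, F, N = _basis_arrays(positions, unit=unit_basis)
    out = np.stack(
        [
            np.einsum("...ij,...j->...i", rel, N),
            np.einsum("...ij,...j->...i", rel, F),
            np.einsum("...ij,...j->...i", rel, S),
        ],
        axis=-1,
    )
    return out


def frame_feature(frame: SkeletonFrame, unit_basis: bool = True) -> np.ndarray:
    """25x3 feature slice for one frame; row i = (f_N, f_F, f_S) of joint i.

    The SHOULDER_RIGHT row is identically zero (it is the origin joint).
    """
    return _frame_features(frame.positions, unit_basis=unit_basis)


def feature_cube(
    seq: SkeletonSequence,
    segment: FusedSegment,
    n_points: int = 60,
    unit_basis: bool = True,
) -> np.ndarray:
    """T x 25 x 3 feature cube over the fused segment.

    Frames inside the segment are linearly resampled to ``n_points`` uniform
    instants (interpolation on joint positions, features computed after), then
    featurized per frame and stacked along time.
    """
    mask = (seq.times >= segment.t_start) & (seq.times <= segment.t_end)
    if mask.sum() < 2:
        raise ValidationError("fewer than 2 skeleton frames inside the fused segment")
    _, positions = resample_uniform(seq.times[mask], seq.positions[mask], n_points)
    return _frame_features(positions, unit_basis=unit_basis)


def flatten_skeleton(cube: np.ndarray) -> np.ndarray:
    """T x 75 sequence: per frame, joints in index order, (N, F, S) per joint."""
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 3 or cube.shape[1:] != (N_JOINTS, 3):
        raise ValidationError(f"expected a (T, 25, 3) cube, got {cube.shape}")
    return cube.reshape(cube.shape[0], N_JOINTS * 3)


def unflatten_skeleton(flat: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_skeleton`."""
    flat = np.asarray(flat, dtype=float)
    return flat.reshape(flat.shape[0], N_JOINTS, 3)


def concat_skeleton(cube: np.ndarray) -> np.ndarray:
    """Single 75*T vector (frame-major), the flat input used by the SVM baseline."""
    return flatten_skeleton(cube).reshape(-1)
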