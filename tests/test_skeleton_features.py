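import numpy as np
import pytest

from mmhar.segmentation import FusedSegment
from mmhar.skeleton import (
    DegenerateSkeletonError,
    body_basis,
    body_height,
    concat_skeleton,
    feature_cube,
    flatten_skeleton,
    frame_feature,
    normalize_joints,
    unflatten_skeleton,
)
from mmhar.types import JointName, N_JOINTS, SkeletonFrame, SkeletonSequence, ValidationError
from conftest import make_frame, make_sequence

HEAD, SL, SR = int(JointName.HEAD), int(JointName.SHOULDER_LEFT), int(JointName.SHOULDER_RIGHT)
FL, FR = int(JointName.FOOT_LEFT), int(JointName.FOOT_RIGHT)


def _rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestBodyHeight:
    def test_head_above_coincident_feet(self, rng):
        frame = make_frame(rng)
        p = frame.positions.copy()
        p[HEAD] = (0, 1.7, 0)
        p[FL] = p[FR] = (0, 0, 0)
        assert body_height(SkeletonFrame(0.0, p)) == pytest.approx(1.7)

    def test_midpoint_at_origin(self, rng):
        p = make_frame(rng).positions.copy()
        p[HEAD] = (0, 1.8, 0)
        p[FL] = (-0.1, 0, 0)
        p[FR] = (0.1, 0, 0)
        assert body_height(SkeletonFrame(0.0, p)) == pytest.approx(1.8)

    def test_degenerate_skeleton_raises(self):
        with pytest.raises(DegenerateSkeletonError):
            body_height(SkeletonFrame(0.0, np.zeros((N_JOINTS, 3))))


class TestNormalizeJoints:
    def test_origin_joint_row_is_zero(self, rng):
        out = normalize_joints(make_frame(rng))
        assert np.allclose(out[SR], 0.0)

    def test_uniform_scaling_invariance(self, rng):
        frame = make_frame(rng)
        scaled = SkeletonFrame(0.0, frame.positions * 2.0)
        assert np.allclose(normalize_joints(frame), normalize_joints(scaled), atol=1e-12)

    def test_matches_naive_per_joint_loop(self, rng):
        frame = make_frame(rng)
        h = body_height(frame)
        out = normalize_joints(frame)
        for i in range(N_JOINTS):
            expected = (frame.positions[i] - frame.positions[SR]) / h
            assert np.allclose(out[i], expected, atol=1e-12)


class TestBodyBasis:
    def test_axis_aligned_cross_product(self, rng):
        p = make_frame(rng).positions.copy()
        p[SR] = (0, 0, 0)
        p[SL] = (0.4, 0, 0)
        p[FL] = (-0.1, -1.5, 0)
        p[FR] = (0.1, -1.5, 0)
        basis = body_basis(SkeletonFrame(0.0, p))
        assert np.allclose(basis.S, (1, 0, 0), atol=1e-12)
        assert np.allclose(basis.F, (0, -1, 0), atol=1e-12)
        assert np.allclose(basis.N, (0, 0, -1), atol=1e-12)

    def test_orthogonality_and_unit_norm(self, rng):
        basis = body_basis(make_frame(rng))
        for v in (basis.S, basis.F, basis.N):
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)
        assert abs(basis.N @ basis.S) < 1e-9
        assert abs(basis.N @ basis.F) < 1e-9

    def test_cross_product_matches_cofactor_formula(self, rng):
        frame = make_frame(rng)
        basis = body_basis(frame, unit=False)
        s, f = basis.S, basis.F
        cof = np.array(
            [s[1] * f[2] - s[2] * f[1], s[2] * f[0] - s[0] * f[2], s[0] * f[1] - s[1] * f[0]]
        )
        assert np.allclose(basis.N, cof, atol=1e-12)

    def test_parallel_vectors_raise(self, rng):
        p = make_frame(rng).positions.copy()
        p[SR] = (0, 0, 0)
        p[SL] = (1, 0, 0)
        p[FL] = p[FR] = (2, 0, 0)  # foot midpoint collinear with shoulders
        with pytest.raises(DegenerateSkeletonError):
            body_basis(SkeletonFrame(0.0, p))


class TestFrameFeature:
    def test_origin_joint_projects_to_zero(self, rng):
        assert np.allclose(frame_feature(make_frame(rng))[SR], 0.0, atol=1e-12)

    def test_unit_shoulder_direction_projects_to_001(self, rng):
        # S and F are only mutually orthogonal in special poses; use one so the
        # on-axis projection is exactly (0, 0, 1).  In a generic pose the row
        # is (0, <F,S>, 1) because the basis is not orthogonalized.
        p = make_frame(rng).positions.copy()
        p[SR] = (0.0, 1.4, 0.0)
        p[SL] = (0.4, 1.4, 0.0)
        p[FL] = (-0.1, 0.0, 0.0)
        p[FR] = (0.1, 0.0, 0.0)  # foot midpoint straight below SR -> F = -y
        frame = SkeletonFrame(0.0, p)
        h = body_height(frame)
        basis = body_basis(frame)
        assert abs(basis.F @ basis.S) < 1e-12
        p2 = p.copy()
        p2[int(JointName.HAND_LEFT)] = p[SR] + h * basis.S
        row = frame_feature(SkeletonFrame(0.0, p2))[int(JointName.HAND_LEFT)]
        assert np.allclose(row, (0, 0, 1), atol=1e-9)

    def test_matches_naive_dot_product_loop(self, rng):
        frame = make_frame(rng)
        out = frame_feature(frame)
        rel = normalize_joints(frame)
        basis = body_basis(frame)
        for i in range(N_JOINTS):
            expected = [float(basis.N @ rel[i]), float(basis.F @ rel[i]), float(basis.S @ rel[i])]
            assert np.allclose(out[i], expected, atol=1e-12)


class TestInvariances:
    """Global translation / rotation / uniform scaling leave features unchanged."""

    def test_translation(self, rng):
        frame = make_frame(rng)
        moved = SkeletonFrame(0.0, frame.positions + np.array([3.0, -1.0, 2.5]))
        assert np.allclose(frame_feature(frame), frame_feature(moved), atol=1e-9)

    def test_rotation(self, rng):
        frame = make_frame(rng)
        rot = SkeletonFrame(0.0, frame.positions @ _rotation(rng).T)
        assert np.allclose(frame_feature(frame), frame_feature(rot), atol=1e-9)

    def test_uniform_scaling(self, rng):
        frame = make_frame(rng)
        scaled = SkeletonFrame(0.0, frame.positions * 1.37)
        assert np.allclose(frame_feature(frame), frame_feature(scaled), atol=1e-9)


class TestFeatureCube:
    def test_static_pose_gives_identical_slices(self, rng):
        positions = np.tile(make_frame(rng).positions, (10, 1, 1))
        seq = SkeletonSequence(times=np.arange(10) / 30, positions=positions, rate_hz=30)
        cube = feature_cube(seq, FusedSegment(0.0, 9 / 30), n_points=6)
        assert cube.shape == (6, 25, 3)
        assert np.allclose(cube, cube[0], atol=1e-12)

    def test_default_shape_contract(self, rng):
        seq = make_sequence(rng, n_frames=80)
        cube = feature_cube(seq, FusedSegment(seq.times[0], seq.times[-1]), n_points=60)
        assert cube.shape == (60, 25, 3)

    def test_resample_then_featurize_order(self, rng):
        from mmhar.segmentation import resample_uniform
        from mmhar.skeleton import _frame_features

        seq = make_sequence(rng, n_frames=30)
        seg = FusedSegment(seq.times[2], seq.times[-3])
        cube = feature_cube(seq, seg, n_points=12)
        mask = (seq.times >= seg.t_start) & (seq.times <= seg.t_end)
        _, pos = resample_uniform(seq.times[mask], seq.positions[mask], 12)
        expected = np.stack([_frame_features(pos[t]) for t in range(12)])
        assert np.allclose(cube, expected, atol=1e-12)

    def test_too_few_frames_in_segment(self, rng):
        seq = make_sequence(rng, n_frames=10)
        with pytest.raises(ValidationError):
            feature_cube(seq, FusedSegment(100.0, 101.0), n_points=6)


class TestFlatten:
    def test_zero_cube(self):
        flat = flatten_skeleton(np.zeros((4, 25, 3)))
        assert flat.shape == (4, 75) and np.all(flat == 0)

    def test_ordering_contract(self, rng):
        cube = np.zeros((2, 25, 3))
        cube[0, 1, 1] = 7.0  # joint index 1, F component
        assert flatten_skeleton(cube)[0, 4] == 7.0

    def test_bijection(self, rng):
        cube = rng.normal(size=(5, 25, 3))
        assert np.array_equal(unflatten_skeleton(flatten_skeleton(cube)), cube)

    def test_concat_mode_is_frame_major(self, rng):
        cube = rng.normal(size=(3, 25, 3))
        vec = concat_skeleton(cube)
        assert vec.shape == (225,)
        assert np.array_equal(vec[:75], flatten_skeleton(cube)[0])
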