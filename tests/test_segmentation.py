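import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mmhar.segmentation import (
    DifferenceSeries,
    NoActivityError,
    SegmentationConfig,
    Span,
    centroid_difference_series,
    compute_centroid,
    detect_span,
    fuse_spans,
    imu_difference_series,
    resample_uniform,
    segment_trial,
)
from mmhar.types import N_JOINTS, SkeletonFrame, SkeletonSequence, ValidationError
from conftest import make_frame, make_sequence, make_stream, make_trial


class TestCentroid:
    def test_constant_joints(self):
        frame = SkeletonFrame(t=0.0, positions=np.tile([1.0, 2.0, 3.0], (N_JOINTS, 1)))
        assert np.allclose(compute_centroid(frame), [1.0, 2.0, 3.0])
        frame0 = SkeletonFrame(t=0.0, positions=np.zeros((N_JOINTS, 3)))
        assert np.allclose(compute_centroid(frame0), 0.0)

    def test_matches_naive_per_axis_mean(self, rng):
        frame = make_frame(rng)
        naive = np.zeros(3)
        for i in range(N_JOINTS):
            for a in range(3):
                naive[a] += frame.positions[i, a]
        naive /= N_JOINTS
        assert np.allclose(compute_centroid(frame), naive, atol=1e-12)


class TestDifferenceSeries:
    def test_static_sequence_is_all_zero(self, rng):
        positions = np.tile(make_frame(rng).positions, (5, 1, 1))
        seq = SkeletonSequence(times=np.arange(5) / 30, positions=positions, rate_hz=30)
        assert np.allclose(centroid_difference_series(seq).values, 0.0)

    def test_three_four_five_step(self):
        positions = np.zeros((4, N_JOINTS, 3))
        for t in range(4):
            positions[t, :, 0] = 0.3 * t
            positions[t, :, 2] = 0.4 * t
        seq = SkeletonSequence(times=np.arange(4.0), positions=positions, rate_hz=1)
        assert np.allclose(centroid_difference_series(seq).values, 0.5)

    def test_alternating_gyro_unit_steps(self, rng):
        stream = make_stream(rng, n=6)
        stream.gyro = np.array([[i % 2, 0, 0] for i in range(6)], dtype=float)
        assert np.allclose(imu_difference_series(stream, "gyro").values, 1.0)

    @pytest.mark.parametrize("channel", ["gyro", "accel"])
    def test_matches_naive_two_sample_recomputation(self, rng, channel):
        stream = make_stream(rng, n=40)
        series = imu_difference_series(stream, channel)
        sig = stream.gyro if channel == "gyro" else stream.accel
        for i in range(1, 40):
            d = np.sqrt(sum((sig[i, a] - sig[i - 1, a]) ** 2 for a in range(3)))
            assert series.values[i - 1] == pytest.approx(d, abs=1e-12)
            assert series.t[i - 1] == stream.times[i]

    def test_offset_invariance(self, rng):
        stream = make_stream(rng, n=30)
        base = imu_difference_series(stream, "accel").values
        stream.accel = stream.accel + np.array([5.0, -3.0, 11.0])
        assert np.allclose(imu_difference_series(stream, "accel").values, base, atol=1e-9)

    def test_too_short_inputs_rejected(self, rng):
        seq = make_sequence(rng, n_frames=2)
        seq.times, seq.positions = seq.times[:1], seq.positions[:1]  # bypass ctor check
        with pytest.raises(ValidationError):
            centroid_difference_series(seq)


class TestDetectSpan:
    def test_all_zero_series_gives_none(self):
        series = DifferenceSeries(t=np.arange(5.0), values=np.zeros(5), source="depth")
        assert detect_span(series) is None

    def test_hand_evaluated_threshold_rule(self):
        # threshold = 0.05 * 1.0; 0.02 and zeros are not above it
        series = DifferenceSeries(
            t=np.arange(1.0, 8.0),
            values=np.array([0.0, 0.0, 1.0, 0.8, 0.02, 0.0, 0.0]),
            source="depth",
        )
        span = detect_span(series, SegmentationConfig(threshold_fraction=0.05))
        assert (span.t_start, span.t_end) == (3.0, 4.0)

    def test_single_nonzero_value_degenerate_span(self):
        series = DifferenceSeries(t=np.arange(4.0), values=np.array([0, 0, 0.7, 0]), source="x")
        span = detect_span(series)
        assert span.t_start == span.t_end == 2.0

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        values = np.array([0.0, 0.1, 1.0, 0.3, 0.04, 0.0])
        base = detect_span(DifferenceSeries(np.arange(6.0), values, "x"))
        scaled = detect_span(DifferenceSeries(np.arange(6.0), values * scale, "x"))
        assert (base.t_start, base.t_end) == (scaled.t_start, scaled.t_end)


class TestFuseSpans:
    def test_single_span_identity(self):
        seg = fuse_spans([Span(2.0, 5.0, "a")])
        assert (seg.t_start, seg.t_end) == (2.0, 5.0)

    def test_min_start_max_end(self):
        seg = fuse_spans([Span(2, 5, "a"), Span(3, 9, "b"), Span(1, 4, "c")])
        assert (seg.t_start, seg.t_end) == (1.0, 9.0)
        assert len(seg.contributing) == 3

    def test_matches_exhaustive_scan_on_nine_spans(self, rng):
        spans = []
        for i in range(9):
            a, b = sorted(rng.uniform(0, 10, 2))
            spans.append(Span(a, b, f"s{i}"))
        seg = fuse_spans(spans)
        lo = min(s.t_start for s in spans)
        hi = max(s.t_end for s in spans)
        assert (seg.t_start, seg.t_end) == (lo, hi)
        assert all(s in seg.contributing for s in spans)

    def test_empty_input_raises_no_activity(self):
        with pytest.raises(NoActivityError):
            fuse_spans([])


class TestSegmentTrial:
    def test_static_trial_raises_no_activity(self, rng):
        trial = make_trial(rng)
        trial.skeleton.positions = np.tile(trial.skeleton.positions[:1], (len(trial.skeleton), 1, 1))
        for s in trial.imu.values():
            s.gyro = np.zeros_like(s.gyro)
            s.accel = np.zeros_like(s.accel)
        with pytest.raises(NoActivityError):
            segment_trial(trial)

    def test_static_skeleton_falls_back_to_imu_union(self, rng):
        trial = make_trial(rng, n_samples=100)
        trial.skeleton.positions = np.tile(trial.skeleton.positions[:1], (len(trial.skeleton), 1, 1))
        for s in trial.imu.values():
            s.gyro = np.zeros_like(s.gyro)
            s.accel = np.zeros_like(s.accel)
            s.gyro[40:61, 0] = np.sin(np.arange(21))  # active burst mid-stream
        seg = segment_trial(trial)
        spans = [s for s in seg.contributing if s.source.startswith("gyro")]
        assert seg.t_start == min(s.t_start for s in spans)
        assert seg.t_end == max(s.t_end for s in spans)

    def test_recovers_generated_activity_window(self, synthetic_trial):
        trial, truth = synthetic_trial
        seg = segment_trial(trial)
        t0, t1 = truth["active_window"]
        delta = 2.0 / trial.skeleton.rate_hz  # two inter-sample intervals
        assert t0 - delta <= seg.t_start <= t0 + delta
        assert t1 - delta <= seg.t_end <= t1 + delta


class TestResampleUniform:
    def test_constant_series(self):
        t, v = resample_uniform(np.array([0.0, 1.0, 3.0]), np.full((3, 2), 4.0), 7)
        assert np.allclose(v, 4.0) and len(t) == 7

    def test_linear_ramp(self):
        _, v = resample_uniform(np.array([0.0, 1.0]), np.array([0.0, 10.0]).reshape(2), 5)
        assert np.allclose(v, [0, 2.5, 5, 7.5, 10])

    def test_identity_on_uniform_grid(self, rng):
        times = np.linspace(0, 2, 9)
        values = rng.normal(size=(9, 3))
        _, v = resample_uniform(times, values, 9)
        assert np.allclose(v, values, atol=1e-12)

    def test_endpoints_exact_and_npoints_validated(self, rng):
        times = np.sort(rng.uniform(0, 5, 11))
        values = rng.normal(size=(11, 4))
        _, v = resample_uniform(times, values, 6)
        assert np.array_equal(v[0], values[0]) and np.array_equal(v[-1], values[-1])
        with pytest.raises(ValidationError):
            resample_uniform(times, values, 1)
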