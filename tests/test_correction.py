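"""Unit and property tests for the scale/rotation/resampling pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bellkin import correction, synthetic
from bellkin.types import DigitizedFrame, SequenceConfig, ValidationError
from conftest import half


def frame(points, idx=1, time=0.0, **kw):
    return DigitizedFrame(frame_index=idx, time=time, points=np.asarray(points, float), **kw)


def line_outline(length, n=7, y=0.0):
    x = np.linspace(0.0, length, n)
    return np.column_stack([x, np.full(n, y)])


class TestPolylineArclength:
    def test_three_four_five(self):
        assert correction.polyline_arclength([(0, 0), (3, 4)]) == pytest.approx(5.0)

    def test_single_point_is_zero(self):
        assert correction.polyline_arclength([(2.0, 1.0)]) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            correction.polyline_arclength(np.empty((0, 2)))

    def test_semicircle_approaches_pi(self):
        th = np.linspace(0, np.pi, 51)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        assert correction.polyline_arclength(pts) == pytest.approx(np.pi, rel=2e-3)

    @given(st.floats(0.1, 50.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_homogeneous_under_scaling(self, c, seed):
        pts = np.random.default_rng(seed).normal(size=(8, 2))
        assert correction.polyline_arclength(c * pts) == pytest.approx(
            c * correction.polyline_arclength(pts), rel=1e-9
        )


class TestReferenceScale:
    def test_stationary_reference_gives_unity(self):
        frames = [
            frame(line_outline(1.0), idx=i, time=0.2 * i, reference_xy=(50.0, 10.0))
            for i in range(1, 4)
        ]
        s = correction.reference_scale(frames, frame_center_x=320.0)
        assert np.allclose(s.s_ref, 1.0)

    def test_doubled_distance_halves_scale(self):
        frames = [
            frame(line_outline(1.0), idx=1, reference_xy=(220.0, 0.0)),
            frame(line_outline(1.0), idx=2, time=0.2, reference_xy=(120.0, 0.0)),
        ]
        s = correction.reference_scale(frames, frame_center_x=320.0)
        assert s.s_ref[1] == pytest.approx(0.5)

    def test_reference_at_center_is_degenerate(self):
        frames = [frame(line_outline(1.0), reference_xy=(320.0, 0.0))]
        with pytest.raises(ValidationError):
            correction.reference_scale(frames, frame_center_x=320.0)

    def test_recovers_synthetic_zoom(self):
        cam = synthetic.CameraSpec(zoom_total=1.3)
        scene = synthetic.make_scene(camera=cam, n_cycles=1, seed=0)
        s = correction.reference_scale(scene.frames, scene.config.frame_center_x)
        assert np.allclose(s.s_ref, 1.0 / scene.true_magnification, rtol=0.01)


class TestArclengthLFScale:
    def test_equal_contracted_arclengths_give_unity(self):
        frames = [
            frame(line_outline(2.0), idx=i, time=float(i - 1)) for i in range(1, 4)
        ]
        s = correction.arclength_lf_scale(frames, [1, 3])
        assert np.allclose(s.s_lf, 1.0)

    def test_exact_line_through_contracted_points(self):
        # contracted arclengths 1.0, 1.1, 1.2 at t = 0, 1, 2 -> s_lf = 1/(1+0.1t)
        frames = [
            frame(line_outline(1.0 + 0.1 * t), idx=t + 1, time=float(t)) for t in range(3)
        ]
        s = correction.arclength_lf_scale(frames, [1, 2, 3])
        t = np.array([0.0, 1.0, 2.0])
        assert np.allclose(s.s_lf, 1.0 / (1.0 + 0.1 * t), atol=1e-12)

    def test_too_few_contracted_frames(self):
        with pytest.raises(ValidationError):
            correction.arclength_lf_scale([frame(line_outline(1.0))], [1])

    def test_removes_planted_linear_drift(self, corrupted_scene, corrupted_corrected):
        halves, _, _ = corrupted_corrected
        totals = {}
        for h in halves:
            totals[h.frame_index] = totals.get(h.frame_index, 0.0) + h.arclength
        L = np.array([totals[f] for f in corrupted_scene.config.contracted_frames])
        assert np.std(L) / np.mean(L) < 0.005


class TestLocateApex:
    def test_marker_on_outline_zero_offset(self):
        pts = line_outline(10.0, n=11)
        fr = frame(pts, marker_xy=(5.0, 0.0))
        apex, a, b = correction.locate_apex(fr)
        assert np.allclose(apex, (5.0, 0.0))

    def test_symmetric_profile_splits_evenly(self):
        th = np.linspace(np.pi, 0.0, 41)
        dome = np.column_stack([np.cos(th), np.sin(th)])
        fr = frame(dome, marker_xy=(0.0, 1.0))
        apex, a, b = correction.locate_apex(fr)
        la = correction.polyline_arclength(a)
        lb = correction.polyline_arclength(b)
        assert abs(la - lb) / max(la, lb) < 0.01

    def test_offset_beyond_outline_raises(self):
        fr = frame(line_outline(10.0, n=11), marker_xy=(5.0, 0.0))
        with pytest.raises(ValidationError):
            correction.locate_apex(fr, apex_offset=6.0, offset_sign=1)


class TestBodyAngle:
    def test_horizontal_top_gives_zero(self):
        a = half(line_outline(1.0)).points
        bf = correction.body_angle(a, a.copy(), apex_xy=(0.0, 0.0))
        assert bf.theta == pytest.approx(0.0, abs=1e-12)

    def test_exact_equivariance_on_collinear_points(self):
        a = line_outline(1.0)
        rot = np.radians(10.0)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        bf0 = correction.body_angle(a, a.copy(), (0, 0))
        bf1 = correction.body_angle(a @ R.T, (a @ R.T).copy(), (0, 0))
        assert bf1.theta - bf0.theta == pytest.approx(rot, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        a = np.column_stack([np.linspace(0, 1, 20), 0.2 * rng.normal(size=20)])
        bf1 = correction.body_angle(a, a[::-1], (0, 0))
        bf2 = correction.body_angle(5.0 * a, 5.0 * a[::-1], (0, 0))
        assert bf1.theta == pytest.approx(bf2.theta, abs=1e-12)

    def test_vertical_collinear_raises(self):
        a = np.column_stack([np.zeros(10), np.linspace(0, 1, 10)])
        with pytest.raises(ValidationError):
            correction.body_angle(a, a.copy(), (0, 0))

    def test_recovers_planted_roll(self, corrupted_scene, corrupted_corrected):
        _, _, body_frames = corrupted_corrected
        est = np.degrees([bf.theta for bf in body_frames])
        assert np.max(np.abs(est - corrupted_scene.true_roll_deg)) < 0.5


class TestToBodyFrame:
    def test_zero_theta_is_pure_translation(self):
        bf = correction.body_angle(line_outline(1.0), line_outline(1.0), (0.5, 0.2))
        out = correction.to_body_frame([(1.5, 0.2)], bf)
        assert np.allclose(out, [(1.0, 0.0)])

    def test_quarter_turn_convention(self):
        from bellkin.types import BodyFrame

        bf = BodyFrame(theta=np.pi / 2 - 1e-12, apex_xy=(0, 0), slope=1e12, intercept=0, n_points=2)
        out = correction.to_body_frame([(1.0, 0.0)], bf)
        assert np.allclose(out, [(0.0, -1.0)], atol=1e-9)

    @given(st.floats(-1.4, 1.4), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_isometry(self, theta, seed):
        from bellkin.types import BodyFrame

        pts = np.random.default_rng(seed).normal(size=(10, 2))
        bf = BodyFrame(theta=theta, apex_xy=(0.3, -0.4), slope=np.tan(theta), intercept=0, n_points=5)
        out = correction.to_body_frame(pts, bf)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.allclose(d_in, d_out, rtol=1e-12, atol=1e-12)


class TestSmoothing:
    def arc(self, n=101, r=2.0):
        th = np.linspace(0.1, 1.3, n)
        return r * np.column_stack([np.cos(th), np.sin(th)])

    def test_constant_radius_arc_unchanged(self):
        pts = np.vstack([[0.0, 0.0], self.arc()])
        h = half(pts)
        out = correction.smooth_half_profile(h)
        assert np.allclose(out.points, h.points, atol=1e-6)

    def test_sinusoid_attenuated_per_butterworth_response(self):
        n = 201
        th = np.linspace(0.1, 1.3, n)
        f = 0.45  # fraction of Nyquist
        ripple = 0.05 * np.sin(np.pi * f * np.arange(n))
        r = 2.0 + ripple
        pts = np.vstack([[0.0, 0.0], np.column_stack([r * np.cos(th), r * np.sin(th)])])
        out = correction.smooth_half_profile(half(pts), cutoff_fraction=0.2)
        r_out = np.hypot(out.points[1:, 0], out.points[1:, 1])
        resid = np.abs(r_out - 2.0)[n // 4 : 3 * n // 4]
        h2 = 1.0 / (1.0 + (f / 0.2) ** 4)  # |H|^2 of the forward-backward pass
        assert resid.max() <= 0.05 * h2 * 2.0  # attenuation at least ~|H|^2

    def test_smoothing_shortens_noisy_convex_arc(self):
        rng = np.random.default_rng(0)
        pts = self.arc(n=80)
        noisy = np.vstack([[0, 0], pts + 0.01 * rng.normal(size=pts.shape)])
        h = half(noisy)
        out = correction.smooth_half_profile(h)
        assert out.arclength <= h.arclength

    def test_too_few_points_raises(self):
        with pytest.raises(ValidationError):
            correction.smooth_half_profile(half(np.random.default_rng(0).normal(size=(5, 2))))


class TestResampling:
    def test_straight_segment_uniform_x(self):
        pts = np.column_stack([np.linspace(0, 10, 25), np.zeros(25)])
        out = correction.resample_half_profile(half(pts), n=51)
        assert np.allclose(out.points[:, 0], 0.2 * np.arange(51), atol=1e-9)

    def test_quarter_circle_arclength(self):
        th = np.linspace(np.pi / 2, 0, 80)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        out = correction.resample_half_profile(half(pts), n=51)
        assert out.arclength == pytest.approx(np.pi / 2, abs=1e-3)

    def test_idempotent_on_uniform_profile(self):
        th = np.linspace(np.pi / 2, 0, 60)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        once = correction.resample_half_profile(half(pts), n=51)
        twice = correction.resample_half_profile(once, n=51)
        assert np.allclose(once.points, twice.points, atol=1e-6)

    def test_small_n_raises(self):
        with pytest.raises(ValidationError):
            correction.resample_half_profile(half(line_outline(1.0)), n=2)

    def test_endpoints_preserved(self):
        th = np.linspace(1.4, 0.1, 33)
        pts = np.column_stack([np.cos(th), np.sin(th)])
        out = correction.resample_half_profile(half(pts), n=21)
        assert np.array_equal(out.points[0], pts[0])
        assert np.array_equal(out.points[-1], pts[-1])


class TestCorrectSequence:
    def test_identity_camera_is_noop_correction(self, clean_scene, clean_corrected):
        halves, scales, body_frames = clean_corrected
        assert np.allclose(scales.s_total, 1.0, atol=1e-9)
        assert np.max(np.abs([bf.theta for bf in body_frames])) < np.radians(0.3)
        # normalized relaxed half arclength should sit at ~1 (the truth's unit)
        relaxed = [h for h in halves if h.frame_index == 1]
        assert np.mean([h.arclength for h in relaxed]) == pytest.approx(1.0, abs=1e-9)

    def test_margin_trajectories_overlay_between_cycles(
        self, corrupted_scene, corrupted_corrected
    ):
        halves, scales, bfs = corrupted_corrected
        rep = synthetic.recovery_report(corrupted_scene, halves, scales, bfs)
        assert rep["margin_overlay_pct"] < 2.0

    def test_missing_reference_degrades_with_warning(self, clean_scene, caplog):
        frames = [
            DigitizedFrame(f.frame_index, f.time, f.points, None, f.marker_xy)
            for f in clean_scene.frames
        ]
        import logging

        with caplog.at_level(logging.WARNING, logger="bellkin.correction"):
            halves, scales, _ = correction.correct_sequence(frames, clean_scene.config)
        assert np.allclose(scales.s_ref, 1.0)
        assert any("reference" in r.message for r in caplog.records)
        assert len(halves) == 2 * len(frames)
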