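"""Camera calibration model, pupil extraction, and gaze estimation."""

import numpy as np
import pytest

from goggleskit import synth
from goggleskit.eyetrack import (
    CalibrationParams,
    EyeFramePoints,
    camera_to_eye,
    eye_to_camera,
    fit_calibration,
    gaze_pipeline,
    gaze_to_field,
    motion_correct,
    pupil_radius_from_geometry,
    pupil_state,
    pupil_to_gaze,
)


class TestForwardModel:
    def test_origin_fixed_point(self, calib):
        assert np.allclose(eye_to_camera((0.0, 0.0), calib), 0.0)

    def test_odd_symmetry_when_untilted(self):
        par = CalibrationParams(a=0.05, b=0.8, c=0.0, d=15.0, k=400.0)
        e = np.array([0.7, -0.4])
        assert np.allclose(eye_to_camera(-e, par), -eye_to_camera(e, par), atol=1e-12)

    def test_small_angle_series(self):
        # with a=0, c=0 and d >> r^2 the model linearizes to k*b*r*e/sqrt(d)
        par = CalibrationParams(a=0.0, b=1.0, c=0.0, d=1e6, k=500.0)
        e = np.array([0.01, 0.005])
        r = np.hypot(*e)
        expected = par.k * par.b * r * e / np.sqrt(par.d)
        assert np.allclose(eye_to_camera(e, par), expected, rtol=1e-6)

    def test_domain_error_identifies_point(self, calib):
        with pytest.raises(ValueError, match="index 1"):
            eye_to_camera(np.array([[0.1, 0.1], [50.0, 50.0]]), calib)


class TestInverse:
    def test_round_trip_grid(self, calib, mm_grid):
        p = eye_to_camera(mm_grid, calib)
        back = camera_to_eye(p, calib)
        assert np.abs(back - mm_grid).max() < 1e-6

    def test_origin(self, calib):
        assert np.allclose(camera_to_eye((0.0, 0.0), calib), 0.0)

    def test_monotone_radial(self, calib):
        radii = np.linspace(0.1, 1.5, 8)
        norms = [
            np.linalg.norm(eye_to_camera((r / np.sqrt(2), r / np.sqrt(2)), calib))
            for r in radii
        ]
        assert np.all(np.diff(norms) > 0)


class TestFitCalibration:
    def test_parameter_recovery_noiseless(self, calib, mm_grid):
        obs = eye_to_camera(mm_grid, calib)
        fitted, rms = fit_calibration(mm_grid, obs)
        assert rms < 0.1
        pred = eye_to_camera(mm_grid, fitted)
        assert np.abs(pred - obs).max() < 0.1

    def test_noisy_labels_bounded_rms(self, calib, mm_grid):
        rng = np.random.default_rng(0)
        obs = eye_to_camera(mm_grid, calib) + rng.normal(0, 0.5, (len(mm_grid), 2))
        fitted, rms = fit_calibration(mm_grid, obs)
        assert rms == pytest.approx(0.5, abs=0.25)

    def test_degenerate_geometry_rejected(self):
        pts = np.column_stack([np.linspace(-1, 1, 6), np.zeros(6)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            fit_calibration(pts, pts * 100)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_calibration(np.zeros((4, 2)), np.zeros((4, 2)))


class TestPupilState:
    def _frame(self, **pts):
        base = {
            "pupil_left": (10.0, 0.0),
            "pupil_right": (14.0, 0.0),
            "pupil_top": (12.0, 2.0),
            "pupil_bottom": (12.0, -2.0),
            "eyelid_left": (5.0, 0.0),
            "eyelid_right": (19.0, 0.0),
        }
        base.update(pts)
        return EyeFramePoints(points=base)

    def test_center_and_diameter(self):
        s = pupil_state(self._frame())
        assert tuple(s["pupil_center_px"]) == (12.0, 0.0)
        assert s["pupil_diameter_px"] == 4.0
        assert tuple(s["eye_center_px"]) == (12.0, 0.0)

    def test_top_bottom_ignored(self):
        s1 = pupil_state(self._frame())
        s2 = pupil_state(
            self._frame(pupil_top=(999.0, 999.0), pupil_bottom=(-999.0, 0.0))
        )
        assert np.array_equal(s1["pupil_center_px"], s2["pupil_center_px"])
        assert s1["pupil_diameter_px"] == s2["pupil_diameter_px"]

    def test_degenerate_points_give_zero_diameter(self):
        s = pupil_state(self._frame(pupil_left=(12.0, 0.0), pupil_right=(12.0, 0.0)))
        assert s["pupil_diameter_px"] == 0.0
        assert s["valid"]

    def test_low_confidence_flags_invalid(self):
        f = self._frame()
        f.confidence = {"pupil_left": 0.1}
        s = pupil_state(f)
        assert not s["valid"]
        assert "pupil_left" in s["low_confidence"]

    def test_translation_equivariance(self):
        s1 = pupil_state(self._frame())
        shifted = {k: (v[0] + 7.5, v[1] - 3.0) for k, v in self._frame().points.items()}
        s2 = pupil_state(EyeFramePoints(points=shifted))
        assert np.allclose(s2["pupil_center_px"] - s1["pupil_center_px"], [7.5, -3.0])
        assert s1["pupil_diameter_px"] == s2["pupil_diameter_px"]


class TestMotionCorrect:
    def test_stationary_eye_is_identity_up_to_constant(self):
        rng = np.random.default_rng(2)
        pupil = rng.normal(size=(50, 2))
        eye = np.tile([3.0, 4.0], (50, 1))
        out = motion_correct(pupil, eye)
        assert np.allclose(out, pupil)

    def test_common_mode_cancels(self):
        rng = np.random.default_rng(3)
        pupil = rng.normal(size=(200, 2))
        drift = np.column_stack(
            [np.sin(np.linspace(0, 7, 200)), np.cos(np.linspace(0, 5, 200))]
        )
        eye = np.tile([1.0, 1.0], (200, 1)) + drift
        out = motion_correct(pupil + drift, eye)
        # the shared drift is removed exactly, up to the baseline constant
        residual = (out - pupil) - (out - pupil)[0]
        assert np.abs(residual).max() < 1e-9
        exact = motion_correct(pupil + drift, eye, baseline=[1.0, 1.0])
        assert np.abs(exact - pupil).max() < 1e-9


class TestGaze:
    def test_zero_offset(self):
        g = pupil_to_gaze((0.0, 0.0))
        assert (g.yaw_deg, g.pitch_deg) == (0.0, 0.0)

    def test_45_deg_yaw(self):
        g = pupil_to_gaze((1.3, 0.0), p_r=1.3)
        assert g.yaw_deg == pytest.approx(45.0)

    def test_pitch_closed_form(self):
        g = pupil_to_gaze((0.0, 0.3), p_r=1.3)
        assert g.pitch_deg == pytest.approx(np.degrees(np.arctan(0.3 / 1.3)), abs=1e-9)
        assert g.pitch_deg == pytest.approx(12.99, abs=0.01)

    @pytest.mark.parametrize(
        "side, yaw, pitch, expected",
        [
            ("right", 0.0, 0.0, (70.0, 10.0)),
            ("left", 0.0, 0.0, (-70.0, 10.0)),
            ("right", 5.0, -3.0, (75.0, 7.0)),
        ],
    )
    def test_field_mapping(self, side, yaw, pitch, expected):
        from goggleskit.eyetrack import GazeSample

        g = GazeSample(yaw_deg=yaw, pitch_deg=pitch, diameter_mm=1.0)
        assert gaze_to_field(g, side) == pytest.approx(expected)

    def test_pupil_radius_from_printed_geometry(self):
        assert pupil_radius_from_geometry(3.3, 0.375) == pytest.approx(1.3, abs=0.05)


class TestEndToEnd:
    def test_noiseless_recovery(self):
        frames, truth = synth.synth_eye_session(n_frames=60, seed=11)
        gaze = gaze_pipeline(frames, CalibrationParams(**truth["calib"]))
        yaw = np.array([g.yaw_deg for g in gaze])
        pitch = np.array([g.pitch_deg for g in gaze])
        assert np.sqrt(np.mean((yaw - truth["yaw_deg"]) ** 2)) < 0.01
        assert np.sqrt(np.mean((pitch - truth["pitch_deg"]) ** 2)) < 0.01

    def test_recovery_under_label_noise_and_drift(self):
        frames, truth = synth.synth_eye_session(
            n_frames=150, seed=12, label_noise_px=0.5, drift_amp_px=3.0
        )
        gaze = gaze_pipeline(frames, CalibrationParams(**truth["calib"]))
        yaw = np.array([g.yaw_deg for g in gaze])
        pitch = np.array([g.pitch_deg for g in gaze])
        assert np.sqrt(np.mean((yaw - truth["yaw_deg"]) ** 2)) < 1.0
        assert np.sqrt(np.mean((pitch - truth["pitch_deg"]) ** 2)) < 1.0
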