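"""Anatomical frame construction and joint angle derivation."""

import numpy as np
import pytest

from imugait.angles import (
    PelvicVertical,
    cardan_e1_floating_e3,
    compose_cardan,
    hip_angles,
    knee_angles,
    pcs_from_axes,
    pelvic_vertical,
    pelvis_orientation,
    segment_frames,
    truth_angle_series,
)
from imugait.errors import DegenerateAxesError
from imugait.synthesis import generate_trial, truth_solution


class TestPcsFromAxes:
    def test_canonical_axes_give_identity(self):
        f = pcs_from_axes([1, 0, 0], [0, 0, 1])
        np.testing.assert_allclose(f.R, np.eye(3), atol=1e-15)

    def test_rotated_x_axis(self):
        f = pcs_from_axes([0, 1, 0], [0, 0, 1])
        np.testing.assert_allclose(
            f.R, [[0, 1, 0], [-1, 0, 0], [0, 0, 1]], atol=1e-15
        )

    def test_first_row_parallel_to_x_even_when_z_not_orthogonal(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=3)
            z = rng.normal(size=3)
            if np.linalg.norm(np.cross(x, z)) < 1e-3:
                continue
            f = pcs_from_axes(x, z)
            np.testing.assert_allclose(f.R[0], x / np.linalg.norm(x), atol=1e-12)

    def test_parallel_axes_rejected(self):
        with pytest.raises(DegenerateAxesError):
            pcs_from_axes([1, 0, 0], [1e-9, 0, 1e-12])


class TestPelvicVertical:
    def test_level_static_sensor(self):
        R = np.tile(np.eye(3), (50, 1, 1))
        v = pelvic_vertical(R)
        np.testing.assert_allclose(v.v, [0, 0, 1], atol=1e-12)

    def test_constant_30_deg_pitch(self):
        from scipy.spatial.transform import Rotation

        R = np.tile(Rotation.from_euler("x", 30, degrees=True).as_matrix(), (10, 1, 1))
        v = pelvic_vertical(R)
        np.testing.assert_allclose(v.v, [0, np.sin(np.deg2rad(30)), np.cos(np.deg2rad(30))],
                                   atol=1e-12)

    def test_symmetric_oscillation_averages_near_static(self):
        from scipy.spatial.transform import Rotation

        ang = 10 * np.sin(np.linspace(0, 4 * np.pi, 400))
        R = Rotation.from_euler("x", ang[:, None], degrees=True).as_matrix()
        v = pelvic_vertical(R)
        err = np.rad2deg(np.arccos(np.clip(v.v @ [0, 0, 1], -1, 1)))
        assert err < 0.6


class TestPelvisOrientation:
    def test_symmetric_hip_vectors_and_up_vertical_give_identity(self, calibration_trial):
        calib = calibration_trial.truth_calibration
        # construct an idealized calibration: hip vectors symmetric about x
        from imugait.calibration import CalibrationParameters

        jc = dict(calib.jc)
        jc[("lumbar", "hip_r")] = np.array([0.1, 0.0, -0.05])
        jc[("lumbar", "hip_l")] = np.array([-0.1, 0.0, -0.05])
        ideal = CalibrationParameters(jc=jc, axes=dict(calib.axes))
        f = pelvis_orientation(ideal, PelvicVertical(np.array([0.0, 0.0, 1.0])))
        np.testing.assert_allclose(f.R, np.eye(3), atol=1e-12)

    def test_coincident_hip_centers_rejected(self, calibration_trial):
        from imugait.calibration import CalibrationParameters

        jc = dict(calibration_trial.truth_calibration.jc)
        jc[("lumbar", "hip_l")] = jc[("lumbar", "hip_r")].copy()
        bad = CalibrationParameters(jc=jc, axes=dict(calibration_trial.truth_calibration.axes))
        with pytest.raises(DegenerateAxesError):
            pelvis_orientation(bad, PelvicVertical(np.array([0.0, 0.0, 1.0])))


class TestCardan:
    def test_identity_gives_zero_angles(self):
        assert cardan_e1_floating_e3(np.eye(3)) == pytest.approx((0.0, 0.0, 0.0))

    def test_pure_flexion(self):
        R = compose_cardan(30.0, 0.0, 0.0)
        fe, aa, ie = cardan_e1_floating_e3(R)
        assert (fe, aa, ie) == pytest.approx((30.0, 0.0, 0.0), abs=1e-12)

    @pytest.mark.parametrize("side", ["r", "l"])
    def test_round_trip_random_triples(self, side):
        rng = np.random.default_rng(7)
        fe = rng.uniform(-80, 80, 300)
        aa = rng.uniform(-40, 40, 300)
        ie = rng.uniform(-80, 80, 300)
        f2, a2, i2 = cardan_e1_floating_e3(compose_cardan(fe, aa, ie, side), side)
        np.testing.assert_allclose(f2, fe, atol=1e-9)
        np.testing.assert_allclose(a2, aa, atol=1e-9)
        np.testing.assert_allclose(i2, ie, atol=1e-9)


class TestSegmentFrames:
    def test_truth_calibration_recovers_truth_mounts(self, walking_trial):
        frames = segment_frames(walking_trial.truth_calibration)
        for sid in ("thigh_r", "shank_l"):
            R_sm = walking_trial.mounts.rotations[sid]
            np.testing.assert_allclose(frames[sid].R, R_sm, atol=1e-9)

    def test_flipped_knee_axis_negates_x_row_only(self, walking_trial):
        from imugait.calibration import CalibrationParameters

        calib = walking_trial.truth_calibration
        axes = dict(calib.axes)
        axes[("thigh_r", "knee_r")] = -axes[("thigh_r", "knee_r")]
        flipped = CalibrationParameters(jc=dict(calib.jc), axes=axes)
        a = segment_frames(calib)["thigh_r"].R
        b = segment_frames(flipped)["thigh_r"].R
        np.testing.assert_allclose(b[0], -a[0], atol=1e-12)
        np.testing.assert_allclose(b[2], a[2], atol=1e-12)


class TestClosedLoopAngles:
    """Truth states + truth calibration through the angle pipeline must
    reproduce the generator's input profiles."""

    def test_hip_and_knee_recovery_calibration_motion(self, calibration_trial):
        trial = calibration_trial
        sol = truth_solution(trial)
        v = PelvicVertical(trial.mounts.rotations["lumbar"].T @ np.array([0.0, 0.0, 1.0]))
        hip = hip_angles(sol, v=v)
        knee = knee_angles(sol)
        idx = np.arange(0, trial.array.n_samples, 10)
        for side in ("r", "l"):
            th = truth_angle_series(trial, "hip", side, idx)
            tk = truth_angle_series(trial, "knee", side, idx)
            np.testing.assert_allclose(hip[side].flexion, th.flexion, atol=1e-6)
            np.testing.assert_allclose(hip[side].abduction, th.abduction, atol=1e-6)
            np.testing.assert_allclose(hip[side].internal, th.internal, atol=1e-6)
            np.testing.assert_allclose(knee[side].flexion, tk.flexion, atol=1e-6)

    def test_degenerate_gait_keeps_secondary_hip_channels_small(self, degenerate_trial):
        sol = truth_solution(degenerate_trial)
        hip = hip_angles(sol)  # data-driven pelvic vertical
        idx = np.arange(0, degenerate_trial.array.n_samples, 10)
        for side in ("r", "l"):
            th = truth_angle_series(degenerate_trial, "hip", side, idx)
            assert np.max(np.abs(hip[side].abduction)) < 0.5
            assert np.max(np.abs(hip[side].internal)) < 0.5
            rmse = np.sqrt(np.mean((hip[side].flexion - th.flexion) ** 2))
            assert rmse < 1.0

    def test_heading_rotation_invariance(self, walking_trial):
        """Rotating the whole solution about world z changes no angle."""
        from imugait._so3 import rotz

        sol = truth_solution(walking_trial)
        base = knee_angles(sol)["r"].flexion
        Rz = rotz(np.deg2rad(73.0))
        for sid, tr in sol.trajectories.items():
            tr.R = Rz @ tr.R
            tr.p = tr.p @ Rz.T
            tr.v = tr.v @ Rz.T
        rotated = knee_angles(sol)["r"].flexion
        np.testing.assert_allclose(rotated, base, atol=1e-9)
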