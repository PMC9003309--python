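"""Synthetic gait generator: profiles, forward kinematics, inverse sensor
model, soft-tissue injection, determinism."""

import numpy as np
import pytest

from imugait._so3 import expm, logm
from imugait.errors import ArgumentError
from imugait.synthesis import (
    GRAVITY,
    PelvisMotion,
    SkeletonModel,
    SoftTissueSpec,
    calibration_profile,
    forward_kinematics,
    gait_profile,
    generate_trial,
    inject_soft_tissue,
    joint_center_world,
    knee_waveform,
    sensor_poses,
    soft_tissue_offset,
    synthesize_imu,
    truth_calibration,
    default_mounts,
)


class TestGaitProfile:
    def test_cycle_count(self):
        """100 steps/min for 30 s is 25 full gait cycles per leg."""
        prof = gait_profile(30.0, 200.0, cadence=100.0)
        assert prof.cycle_period == pytest.approx(1.2)
        knee = prof.angles["knee_r"][:, 0]
        # count strict local maxima of the dominant swing peak
        big = (knee[1:-1] > knee[:-2]) & (knee[1:-1] > knee[2:]) & (knee[1:-1] > 40)
        assert big.sum() == 25

    def test_antiphase_left_right(self):
        prof = gait_profile(10.0, 200.0, cadence=100.0)
        half = int(0.6 * 200)  # half period in samples
        right = prof.angles["hip_r"][:, 0]
        left = prof.angles["hip_l"][:, 0]
        np.testing.assert_allclose(left[:-half], right[half:], atol=1e-9)

    def test_degenerate_flag_zeroes_hip_secondary_channels(self):
        prof = gait_profile(5.0, 200.0, degenerate_1dof=True)
        for side in ("r", "l"):
            assert np.max(np.abs(prof.angles[f"hip_{side}"][:, 1:])) == 0.0

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ArgumentError):
            gait_profile(5.0, 200.0, hip_fe_amp=-1.0)

    def test_knee_waveform_two_peaks_per_cycle(self):
        ph = np.linspace(0, 1, 4000, endpoint=False)
        k = knee_waveform(ph)
        interior = (k[1:-1] > k[:-2]) & (k[1:-1] > k[2:])
        # dominant swing peak at phase 0 (array edge) plus one stance bump
        assert interior.sum() == 1
        assert k[0] > k.max() - 1e-9


class TestCalibrationProfile:
    def test_hip_channels_sweep_at_least_30_deg(self):
        prof = calibration_profile(60.0, 200.0)
        for side in ("r", "l"):
            hip = prof.angles[f"hip_{side}"]
            for ch in range(3):
                assert np.ptp(hip[:, ch]) >= 30.0
            assert np.ptp(prof.angles[f"knee_{side}"][:, 0]) >= 60.0

    def test_too_short_duration_rejected(self):
        with pytest.raises(ArgumentError):
            calibration_profile(5.0, 200.0)

    def test_starts_at_rest(self):
        prof = calibration_profile(20.0, 200.0)
        for joint, block in prof.angles.items():
            assert np.max(np.abs(block[0])) < 1e-9


class TestForwardKinematics:
    def test_neutral_pose_geometry(self):
        sk = SkeletonModel()
        prof = gait_profile(0.1, 200.0)
        for j in prof.angles:
            prof.angles[j][:] = 0.0
        poses = forward_kinematics(prof, sk, PelvisMotion.none())
        for seg, (R, p) in poses.items():
            np.testing.assert_allclose(R[0], np.eye(3), atol=1e-12)
        hip_r = poses["thigh_r"][1][0]
        hip_l = poses["thigh_l"][1][0]
        assert np.linalg.norm(hip_r - hip_l) == pytest.approx(sk.pelvis_width)

    def test_right_angle_knee_makes_segments_perpendicular(self):
        prof = gait_profile(0.1, 200.0)
        for j in prof.angles:
            prof.angles[j][:] = 0.0
        prof.angles["knee_r"][:, 0] = 90.0
        poses = forward_kinematics(prof, SkeletonModel(), PelvisMotion.none())
        thigh_z = poses["thigh_r"][0][0][:, 2]
        shank_z = poses["shank_r"][0][0][:, 2]
        assert abs(thigh_z @ shank_z) < 1e-12

    @pytest.mark.parametrize("joint", ["hip_r", "hip_l", "knee_r", "knee_l", "ankle_r", "ankle_l"])
    def test_joint_coincidence(self, walking_trial, joint):
        """Both adjacent segments place every joint at the same world point."""
        poses = forward_kinematics(
            walking_trial.truth_angles, walking_trial.skeleton,
            PelvisMotion.walking(100.0),
        )
        a = joint_center_world(poses, walking_trial.skeleton, joint, "proximal")
        b = joint_center_world(poses, walking_trial.skeleton, joint, "distal")
        assert np.max(np.abs(a - b)) < 1e-12


class TestSynthesizeImu:
    def test_stationary_level_sensor_reads_gravity_up(self):
        n = 400
        poses = {sid: (np.tile(np.eye(3), (n, 1, 1)), np.zeros((n, 3)))
                 for sid in ("lumbar", "thigh_r", "thigh_l", "shank_r",
                             "shank_l", "foot_r", "foot_l")}
        arr, _ = synthesize_imu(poses, 200.0)
        np.testing.assert_allclose(arr["lumbar"].gyro, 0.0, atol=1e-12)
        dev = arr["lumbar"].accel[5:-5] - np.array([0.0, 0.0, 9.81])
        assert np.max(np.abs(dev)) < 1e-9

    def test_constant_spin_gyro_norm(self):
        n = 400
        t = np.arange(n) / 200.0
        Rz = expm(np.stack([np.zeros(n), np.zeros(n), t], axis=-1))
        poses = {sid: (Rz.copy(), np.zeros((n, 3)))
                 for sid in ("lumbar", "thigh_r", "thigh_l", "shank_r",
                             "shank_l", "foot_r", "foot_l")}
        arr, _ = synthesize_imu(poses, 200.0)
        np.testing.assert_allclose(
            np.linalg.norm(arr["lumbar"].gyro, axis=1), 1.0, atol=1e-9
        )

    def test_gyro_integration_reproduces_truth_orientation(self, walking_trial):
        """Strapdown-integrated noiseless gyro matches the truth orientation
        to far better than 0.1 degree."""
        rec = walking_trial.array["shank_r"]
        st = walking_trial.truth_states["shank_r"]
        dt = 1.0 / walking_trial.fs
        R = st["R"][0].copy()
        inc = expm(rec.gyro[:-1] * dt)
        for k in range(rec.n_samples - 1):
            R = R @ inc[k]
        err_deg = np.rad2deg(np.linalg.norm(logm(R.T @ st["R"][-1])))
        assert err_deg < 0.1

    def test_accel_propagation_reproduces_truth_position(self, walking_trial):
        rec = walking_trial.array["foot_l"]
        st = walking_trial.truth_states["foot_l"]
        dt = 1.0 / walking_trial.fs
        p, v = st["p"][0].copy(), st["v"][0].copy()
        for k in range(rec.n_samples - 1):
            u = st["R"][k] @ rec.accel[k] + GRAVITY
            p = p + v * dt + 0.5 * u * dt * dt
            v = v + u * dt
        assert np.max(np.abs(p - st["p"][-1])) < 1e-9

    def test_seeded_generation_is_deterministic(self):
        a = generate_trial("walking", seed=3, duration=2.0)
        b = generate_trial("walking", seed=3, duration=2.0)
        for sid in a.array.recordings:
            np.testing.assert_array_equal(a.array[sid].gyro, b.array[sid].gyro)
            np.testing.assert_array_equal(a.array[sid].accel, b.array[sid].accel)


class TestTruthCalibration:
    def test_hip_vectors_match_forward_kinematics_geometry(self, walking_trial):
        """sensor position + R @ s lands on the joint center at every sample."""
        trial = walking_trial
        poses = forward_kinematics(trial.truth_angles, trial.skeleton,
                                   PelvisMotion.walking(100.0))
        sposes = sensor_poses(poses, trial.mounts)
        for joint, (prox, dist) in (
            ("hip_r", ("lumbar", "thigh_r")), ("knee_l", ("thigh_l", "shank_l")),
        ):
            cw = joint_center_world(poses, trial.skeleton, joint, "proximal")
            for sid in (prox, dist):
                R, p = sposes[sid]
                s = trial.truth_calibration.jc[(sid, joint)]
                np.testing.assert_allclose(p + R @ s, cw, atol=1e-12)


class TestSoftTissue:
    def test_zero_amplitude_is_identity(self):
        trial = generate_trial("walking", seed=5, duration=3.0)
        out = inject_soft_tissue(trial, SoftTissueSpec(0.0, 0.0))
        for sid in trial.array.recordings:
            np.testing.assert_array_equal(out.array[sid].gyro, trial.array[sid].gyro)
            np.testing.assert_array_equal(out.array[sid].accel, trial.array[sid].accel)

    def test_offset_is_phase_locked_and_smooth(self):
        spec = SoftTissueSpec(3.0, -2.0, transition=0.05)
        ph = np.linspace(0, 1, 20001, endpoint=False)
        off = soft_tissue_offset(ph, spec)
        # plateaus at the stated levels away from the transitions
        mid_swing = (ph > 0.1) & (ph < 0.3)
        mid_stance = (ph > 0.5) & (ph < 0.9)
        np.testing.assert_allclose(off[mid_swing], -2.0, atol=1e-9)
        np.testing.assert_allclose(off[mid_stance], 3.0, atol=1e-9)
        # transitions pass through the midpoint at the phase boundaries
        assert off[0] == pytest.approx((3.0 - 2.0) / 2, abs=1e-6)
        # C1: finite difference of the derivative stays bounded (no kinks)
        d2 = np.diff(off, 2)
        assert np.max(np.abs(d2)) < 5e-4

    def test_nonphysical_amplitude_rejected(self):
        with pytest.raises(ArgumentError):
            SoftTissueSpec(31.0, 0.0)

    def test_perturbation_only_touches_thigh_and_shank(self):
        trial = generate_trial("walking", seed=5, duration=3.0)
        out = inject_soft_tissue(trial, SoftTissueSpec(3.0, -2.0))
        for sid in ("lumbar", "foot_r", "foot_l"):
            np.testing.assert_array_equal(out.array[sid].gyro, trial.array[sid].gyro)
        assert not np.allclose(out.array["shank_r"].gyro, trial.array["shank_r"].gyro)


class TestTrialFactory:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ArgumentError):
            generate_trial("jogging")

    def test_degenerate_truth_has_zero_hip_ie_rom(self):
        trial = generate_trial("walking", seed=1, duration=2.0, degenerate_1dof=True)
        assert np.ptp(trial.truth_angles.angles["hip_r"][:, 2]) == 0.0

    def test_mount_randomization_changes_mounts_deterministically(self):
        a = default_mounts(seed=4)
        b = default_mounts(seed=4)
        c = default_mounts(seed=5)
        np.testing.assert_array_equal(a.rotations["thigh_r"], b.rotations["thigh_r"])
        assert not np.allclose(a.rotations["thigh_r"], c.rotations["thigh_r"])
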