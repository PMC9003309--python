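"""Estimator internals: residual primitives, Jacobian correctness,
initialization, solver behavior on small problems."""

import numpy as np
import pytest

from imugait._so3 import expm
from imugait.errors import ArgumentError
from imugait.estimator import (
    EstimationProblem,
    ImuState,
    NoiseConfig,
    initialize_states,
    residual_hinge,
    residual_inertial,
    residual_joint_center,
    solve_lm,
)
from imugait.synthesis import generate_trial, synthesize_imu, truth_estimate

from conftest import truth_priors


class TestResidualJointCenter:
    def test_collinear_geometry_is_exact(self):
        a = ImuState(R=np.eye(3), p=np.array([0.0, 0, 0]))
        b = ImuState(R=np.eye(3), p=np.array([0.0, 0, -0.4]))
        r = residual_joint_center(a, b, [0, 0, -0.2], [0, 0, 0.2])
        np.testing.assert_allclose(r, 0.0, atol=1e-15)

    def test_offset_appears_directly(self):
        a = ImuState(R=np.eye(3), p=np.array([0.0, 0, 0]))
        b = ImuState(R=np.eye(3), p=np.array([0.0, 0, -0.5]))
        r = residual_joint_center(a, b, [0, 0, -0.2], [0, 0, 0.2])
        np.testing.assert_allclose(r, [0, 0, 0.1], atol=1e-15)


class TestResidualHinge:
    def test_consistent_rotated_axes_are_exact(self):
        from scipy.spatial.transform import Rotation

        Rb = Rotation.from_euler("z", 45, degrees=True).as_matrix()
        aB = Rb.T @ np.array([1.0, 0, 0])
        a = ImuState(R=np.eye(3))
        b = ImuState(R=Rb)
        np.testing.assert_allclose(
            residual_hinge(a, b, [1, 0, 0], aB), 0.0, atol=1e-12
        )

    def test_orthogonal_axes(self):
        a = ImuState(R=np.eye(3))
        b = ImuState(R=np.eye(3))
        np.testing.assert_allclose(
            residual_hinge(a, b, [1, 0, 0], [0, 1, 0]), [1, -1, 0], atol=1e-15
        )

    def test_non_unit_axis_rejected(self):
        a = ImuState(R=np.eye(3))
        with pytest.raises(ArgumentError):
            residual_hinge(a, a, [2, 0, 0], [1, 0, 0])


class TestResidualInertial:
    def test_self_consistent_propagation_is_zero(self):
        """States produced by propagating the measurements give zero residual."""
        rng = np.random.default_rng(3)
        dt = 0.005
        M = 10
        gyro = rng.normal(0, 1.0, (M, 3))
        accel = rng.normal(0, 2.0, (M, 3))
        cfg = NoiseConfig()
        g = np.array([0, 0, -cfg.gravity])
        R = np.eye(3)
        v = np.array([0.1, -0.2, 0.05])
        p = np.zeros(3)
        state_i = ImuState(R=R.copy(), p=p.copy(), v=v.copy())
        for m in range(M):
            u = R @ accel[m] + g
            p = p + v * dt + 0.5 * u * dt * dt
            v = v + u * dt
            R = R @ expm(gyro[m] * dt)
        state_j = ImuState(R=R, p=p, v=v)
        r = residual_inertial(state_i, state_j, gyro, accel, dt, cfg)
        assert np.max(np.abs(r)) < 1e-9

    def test_position_perturbation_maps_to_position_block(self):
        dt = 0.005
        M = 10
        gyro = np.zeros((M, 3))
        accel = np.tile([0.0, 0.0, 9.81], (M, 1))
        cfg = NoiseConfig()
        i = ImuState(R=np.eye(3))
        j = ImuState(R=np.eye(3), p=np.array([0.1, 0.0, 0.0]))
        r = residual_inertial(i, j, gyro, accel, dt, cfg)
        s_p = cfg.sigma_accel * np.sqrt(M * dt * dt) * (M * dt)
        np.testing.assert_allclose(r[:6], 0.0, atol=1e-12)
        np.testing.assert_allclose(r[6:], [0.1 / s_p, 0, 0], atol=1e-9)


class TestProblemAssembly:
    def test_block_counts_for_one_second_window(self):
        """A 1 s inclusive window at 200 Hz has 21 keyframes at 20 Hz:
        7 x 20 inertial intervals and 6 x 21 joint-center blocks."""
        trial = generate_trial("walking", seed=1, duration=1.005)
        prob = EstimationProblem(trial.array)
        d = prob.describe()
        assert d["n_keyframes"] == 21
        assert d["inertial_intervals"] == 7 * 20
        assert d["joint_center_blocks"] == 6 * 21

    def test_walking_without_priors_logs_identifiability_warning(self, caplog):
        trial = generate_trial("walking", seed=1, duration=1.005)
        import logging

        with caplog.at_level(logging.WARNING, logger="imugait"):
            EstimationProblem(trial.array, kind="walking", priors=None)
        assert any("non-identifiable" in r.message for r in caplog.records)

    def test_empty_window_rejected(self, walking_trial):
        from imugait.estimator import assemble_problem

        with pytest.raises(ArgumentError):
            assemble_problem(walking_trial.array, window=(10, 10))


class TestJacobian:
    def test_analytic_jacobian_matches_finite_differences(self, degenerate_trial):
        prob = EstimationProblem(degenerate_trial.array.slice(0, 401))
        est = truth_estimate(degenerate_trial, prob)
        prob.set_gauge_from(est)
        rng = np.random.default_rng(0)
        est = prob.retract(est, rng.normal(0, 1e-3, prob.n_unknowns))
        r0, J = prob.residuals(est, with_jacobian=True)
        d = rng.normal(0, 1, prob.n_unknowns)
        d /= np.linalg.norm(d)
        h = 1e-6
        fd = (
            prob.residuals(prob.retract(est, h * d))
            - prob.residuals(prob.retract(est, -h * d))
        ) / (2 * h)
        an = J @ d
        assert np.max(np.abs(fd - an)) < 1e-4 * max(1.0, np.max(np.abs(an)))


class TestResidualAtTruth:
    def test_all_whitened_residuals_vanish_on_noiseless_hinge_consistent_gait(
        self, degenerate_trial
    ):
        """At the generator's truth, every measurement residual family of a
        noise-free 1-DOF-hip trial is zero to round-off (oracle equivalence).
        The zero-mean regularizing prior on the non-hip joint-center vectors
        is the one family that is nonzero at truth by design."""
        prob = EstimationProblem(degenerate_trial.array)
        est = truth_estimate(degenerate_trial, prob)
        prob.set_gauge_from(est)
        blocks = prob.residual_blocks(est)
        for family in ("inertial", "joint_center", "hinge", "axis_norm"):
            assert np.max(np.abs(blocks[family])) < 1e-6, family


class TestInitializeStates:
    def test_level_static_sensor_initializes_to_identity(self):
        n = 400
        poses = {sid: (np.tile(np.eye(3), (n, 1, 1)), np.zeros((n, 3)))
                 for sid in ("lumbar", "thigh_r", "thigh_l", "shank_r",
                             "shank_l", "foot_r", "foot_l")}
        arr, _ = synthesize_imu(poses, 200.0)
        trajs = initialize_states(arr)
        err = np.rad2deg(np.arccos(np.clip((np.trace(trajs["lumbar"].R[0]) - 1) / 2, -1, 1)))
        assert err < 0.5

    def test_rolled_sensor_leveling_recovers_roll(self):
        n = 400
        R90 = expm(np.array([np.pi / 2, 0, 0]))
        poses = {sid: (np.tile(R90, (n, 1, 1)), np.zeros((n, 3)))
                 for sid in ("lumbar", "thigh_r", "thigh_l", "shank_r",
                             "shank_l", "foot_r", "foot_l")}
        arr, _ = synthesize_imu(poses, 200.0)
        trajs = initialize_states(arr)
        R0 = trajs["lumbar"].R[0]
        # gravity direction recovered regardless of free heading
        np.testing.assert_allclose(R0[2, :] @ R90[2, :], 1.0, atol=1e-4)

    def test_dead_reckoning_tracks_pure_rotation(self, calibration_trial):
        trajs = initialize_states(calibration_trial.array)
        # lumbar orientation drift over the trial, noiseless gyro: tiny
        from imugait._so3 import logm

        st = calibration_trial.truth_states["lumbar"]
        K = trajs["lumbar"].R.shape[0]
        idx = np.arange(K) * 10
        R_err0 = trajs["lumbar"].R[0] @ st["R"][0].T
        drift = [
            np.rad2deg(np.linalg.norm(logm(R_err0.T @ (trajs["lumbar"].R[k] @ st["R"][idx[k]].T))))
            for k in (K // 2, K - 1)
        ]
        assert max(drift) < 0.1

    def test_too_short_recording_rejected(self):
        trial = generate_trial("walking", seed=1, duration=0.4)
        with pytest.raises(ArgumentError):
            initialize_states(trial.array)


class TestSolveLm:
    def test_stationary_point_converges_immediately_by_absolute_criterion(
        self, degenerate_trial
    ):
        """Re-solving from an already-stationary estimate stops within two
        iterations via the absolute cost-change criterion."""
        prob = EstimationProblem(degenerate_trial.array.slice(0, 401))
        est = truth_estimate(degenerate_trial, prob)
        prob.set_gauge_from(est)
        sol = solve_lm(prob, init=est)
        for _ in range(5):  # polish until the absolute criterion is the stop
            if sol.convergence == "absolute":
                break
            sol = solve_lm(prob, init=sol.estimate)
        sol2 = solve_lm(prob, init=sol.estimate)
        assert sol2.convergence == "absolute"
        assert sol2.iterations <= 2

    def test_small_calibration_solve_recovers_geometry(self, calibration_trial):
        """Noise-free short calibration: hip-connected vectors to a few mm."""
        from imugait.estimator import run_calibration

        calib = run_calibration(calibration_trial.array)
        truth = calibration_trial.truth_calibration
        from imugait.calibration import HIP_JC_KEYS

        errs = [np.linalg.norm(calib.jc[k] - truth.jc[k]) for k in HIP_JC_KEYS]
        assert max(errs) < 0.015

    def test_walking_without_priors_refused(self, walking_trial):
        from imugait.estimator import run_walking

        with pytest.raises(ArgumentError):
            run_walking(walking_trial.array, None)

    def test_gauge_heading_invariance_of_derived_angles(self, degenerate_trial):
        """Rotating the initial state and gauge anchor about world z leaves
        derived knee angles unchanged (relative quantities only)."""
        from imugait._so3 import rotz
        from imugait.angles import knee_angles

        sub = degenerate_trial.array.slice(0, 801)
        priors = truth_priors(degenerate_trial)
        base_prob = EstimationProblem(sub, priors=priors, kind="walking")
        base = solve_lm(base_prob)
        base_fe = knee_angles(base)["r"].flexion

        rot_prob = EstimationProblem(sub, priors=priors, kind="walking")
        est = rot_prob.initial_estimate()
        Rz = rotz(np.deg2rad(40.0))
        est.R = Rz @ est.R
        est.p = est.p @ Rz.T
        est.v = est.v @ Rz.T
        rot_prob.set_gauge_from(est)
        rot = solve_lm(rot_prob, init=est)
        rot_fe = knee_angles(rot)["r"].flexion
        np.testing.assert_allclose(rot_fe, base_fe, atol=1e-4)


class TestRelativeHeadingNonIdentifiability:
    """Without magnetometers, the relative heading between the lumbar and
    thigh sensors is anchored only by kinematic constraints.  In the
    degenerate limit (1-DOF hips, motionless pelvis) a common heading
    rotation of one leg's sensor chain about the vertical through its hip
    center leaves the inertial and joint-center residuals exactly zero: the
    loose hip hinge is the one residual family with heading stiffness."""

    @staticmethod
    def _static_pelvis_trial():
        from imugait.synthesis import PelvisMotion, generate_trial

        return generate_trial(
            "walking", seed=31, duration=5.0, degenerate_1dof=True,
            pelvis_motion=PelvisMotion.none(),
        )

    @staticmethod
    def _rotate_leg(trial, est, psi_deg):
        from imugait._so3 import rotz
        from imugait.estimator import _SID_INDEX

        s_th = _SID_INDEX["thigh_r"]
        # right hip center in world: constant under a static pelvis
        pivot = est.p[s_th][0] + est.R[s_th][0] @ trial.truth_calibration.jc[
            ("thigh_r", "hip_r")
        ]
        Rz = rotz(np.deg2rad(psi_deg))
        for sid in ("thigh_r", "shank_r", "foot_r"):
            s = _SID_INDEX[sid]
            est.R[s] = Rz @ est.R[s]
            est.p[s] = pivot + (est.p[s] - pivot) @ Rz.T
            est.v[s] = est.v[s] @ Rz.T
        return est

    def test_hinge_family_carries_all_heading_stiffness(self):
        """At truth, rotating one leg's heading leaves inertial and
        joint-center residuals at zero while the hip hinge residual grows in
        proportion to the rotation."""
        from imugait.synthesis import truth_estimate

        trial = self._static_pelvis_trial()
        prob = EstimationProblem(trial.array, kind="calibration")
        base = truth_estimate(trial, prob)
        prob.set_gauge_from(base)
        rotated = self._rotate_leg(trial, truth_estimate(trial, prob), 5.0)
        blocks = prob.residual_blocks(rotated)
        assert np.max(np.abs(blocks["inertial"])) < 1e-6
        assert np.max(np.abs(blocks["joint_center"])) < 1e-6
        # hip hinge misalignment ~ psi on a near-horizontal axis, whitened
        # by sigma_hinge_hip
        expected = np.deg2rad(5.0) / prob.cfg.sigma_hinge_hip
        assert np.max(np.abs(blocks["hinge"])) > 0.5 * expected

    def test_heading_disperses_without_hip_hinges(self):
        """With the hip hinge residuals removed, optimization cannot move a
        leg-heading offset: initializations keep their heading (dispersion
        equals the initialization spread)."""
        from imugait._so3 import yaw_of
        from imugait.synthesis import truth_estimate

        trial = self._static_pelvis_trial()
        priors = truth_priors(trial)
        headings = []
        for psi in (-10.0, 0.0, 10.0):
            prob = EstimationProblem(
                trial.array, kind="walking", priors=priors,
                hinge_joints=("knee_r", "knee_l", "ankle_r", "ankle_l"),
            )
            est = self._rotate_leg(trial, truth_estimate(trial, prob), psi)
            prob.set_gauge_from(truth_estimate(trial, prob))
            sol = solve_lm(prob, init=est)
            K = sol.trajectories["lumbar"].R.shape[0]
            headings.append(np.rad2deg(
                yaw_of(sol.trajectories["thigh_r"].R[K // 2])
                - yaw_of(sol.trajectories["lumbar"].R[K // 2])
            ))
        assert np.ptp(headings) > 15.0  # the 20 deg init spread survives
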