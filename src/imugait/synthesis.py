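"""Synthetic lower-body gait: truth kinematics, forward simulation of rigidly
mounted IMUs, and phase-locked soft-tissue perturbations.

The generator produces the two study motions the estimator consumes:

* a *walking* trial — periodic, antiphase left/right profiles with a two-peak
  knee flexion waveform, hinge-like knees and ankles, and (optionally
  degenerate) 3-DOF hips;
* a *calibration* trial — a slow multi-frequency motion that excites all three
  hip DOFs (peak-to-peak >= 30 deg on each channel) and flexes the knees
  through >= 60 deg, which is what makes the hip-connected joint-center
  vectors identifiable.

Angle profiles are low-harmonic trigonometric series, so they are smooth,
periodic and differentiable.  IMU signals are synthesized *discretely
consistently*: the gyro sample at k is the exact SO(3) increment
``Log(R_k^T R_{k+1})/dt`` and the specific force is chosen so that the
discrete strapdown recursion reproduces the continuous truth poses exactly at
the sample grid.  Noiseless closed-loop tests are therefore exact to
round-off rather than O(dt^2).

Conventions: world frame right-handed with z up and gravity (0, 0, -9.81)
m/s^2.  Anatomical frames are x right, y anterior, z proximal for every
segment.  Joint angles are degrees, positive flexion / adduction / internal
rotation for both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from ._so3 import expm, logm
from .calibration import JOINT_PAIRS, CalibrationParameters
from .errors import ArgumentError
from .io import PLACEMENTS, ImuRecording, SensorArray, assemble_array

GRAVITY = np.array([0.0, 0.0, -9.81])

SEGMENT_OF_SENSOR = {
    "lumbar": "pelvis",
    "thigh_r": "thigh_r",
    "thigh_l": "thigh_l",
    "shank_r": "shank_r",
    "shank_l": "shank_l",
    "foot_r": "foot_r",
    "foot_l": "foot_l",
}

#: fraction of the gait cycle (which starts at knee max flexion ~ toe off)
#: spent in swing; the remainder is stance.
SWING_FRACTION = 0.4

# Knee flexion waveform: cosine series over cycle phase, dominant maximum at
# phase 0 (toe off) and a small stance bump near phase 0.5.  Fixture
# constants, not claims about any study population.
_KNEE_C = (25.0, 25.0, 12.0, 1.0)


@dataclass
class SkeletonModel:
    """Segment lengths (m) of a left/right symmetric lower body."""

    pelvis_width: float = 0.24
    thigh_length: float = 0.42
    shank_length: float = 0.43

    def __post_init__(self) -> None:
        if min(self.pelvis_width, self.thigh_length, self.shank_length) <= 0:
            raise ArgumentError("segment lengths must be positive")


@dataclass
class MountSpec:
    """Rigid sensor mounting: rotation sensor frame -> segment frame (as a
    matrix whose columns are the sensor axes in the segment frame) and the
    sensor origin ("lever arm") in the segment frame."""

    rotations: dict[str, np.ndarray]
    levers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for sid, R in self.rotations.items():
            R = np.asarray(R, dtype=float)
            if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-9 or np.linalg.det(R) < 0:
                raise ArgumentError(f"mount rotation for {sid} is not proper orthonormal")
            self.rotations[sid] = R
            self.levers[sid] = np.asarray(self.levers[sid], dtype=float)


def default_mounts(seed: int | None = None) -> MountSpec:
    """Plausible sensor placements with deliberately non-trivial orientations.

    With a seed, mount orientations are additionally perturbed (rotvec
    ~N(0, (10 deg)^2)) to emulate casual strap-on placement.
    """
    rot = {
        "lumbar": Rotation.from_rotvec([0.06, 0.04, -0.08]),
        "thigh_r": Rotation.from_rotvec([0.30, -0.15, 0.35]),
        "thigh_l": Rotation.from_rotvec([-0.25, 0.20, -0.30]),
        "shank_r": Rotation.from_rotvec([0.20, 0.25, -0.15]),
        "shank_l": Rotation.from_rotvec([-0.18, -0.22, 0.28]),
        "foot_r": Rotation.from_rotvec([0.10, -0.12, 0.20]),
        "foot_l": Rotation.from_rotvec([-0.14, 0.10, -0.16]),
    }
    lev = {
        "lumbar": [0.0, -0.09, 0.06],
        "thigh_r": [0.06, 0.03, -0.20],
        "thigh_l": [-0.06, 0.03, -0.21],
        "shank_r": [0.04, 0.02, -0.17],
        "shank_l": [-0.04, 0.02, -0.18],
        "foot_r": [0.01, 0.07, -0.03],
        "foot_l": [-0.01, 0.07, -0.03],
    }
    if seed is not None:
        rng = np.random.default_rng(seed)
        for sid in rot:
            rot[sid] = rot[sid] * Rotation.from_rotvec(rng.normal(0.0, np.deg2rad(10.0), 3))
    return MountSpec(
        rotations={sid: r.as_matrix() for sid, r in rot.items()},
        levers={sid: np.asarray(v, dtype=float) for sid, v in lev.items()},
    )


@dataclass
class JointAngleProfiles:
    """Ground-truth joint angle channels (deg), bilateral-positive convention.

    ``angles[joint]`` is (N, 3): flexion/extension, ab/adduction,
    internal/external.  Hinge joints (knee, ankle) use only the first channel.
    """

    t: np.ndarray
    angles: dict[str, np.ndarray]
    cadence: float = 0.0  # steps/min; 0 for non-periodic (calibration) profiles

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for j, a in self.angles.items():
            a = np.asarray(a, dtype=float)
            if a.shape != (self.t.shape[0], 3) or not np.all(np.isfinite(a)):
                raise ArgumentError(f"bad angle channel block for {j}")
            self.angles[j] = a

    @property
    def cycle_period(self) -> float:
        """Gait cycle period per leg (s); 0 if not a gait profile."""
        return 0.0 if self.cadence == 0 else 120.0 / self.cadence


@dataclass
class PelvisMotion:
    """Bounded pelvis oscillation: sinusoids per translation/rotation channel.

    Walking uses small amplitudes locked to the gait cycle rate; the
    calibration task uses larger, slower sweeps — the subject rocks and turns
    the trunk, which is what makes the lumbar-to-hip-center vectors
    observable (a perfectly static pelvis leaves them structurally free).
    All rotations are zero-mean.
    """

    vertical_amp: float = 0.02  # m
    vertical_freq: float = 1.667  # Hz
    lateral_amp: float = 0.025  # m
    lateral_freq: float = 0.833  # Hz
    roll_amp: float = 1.5  # deg
    roll_freq: float = 0.833  # Hz
    pitch_amp: float = 2.0  # deg
    pitch_freq: float = 1.667  # Hz
    yaw_amp: float = 1.0  # deg, zero-mean heading
    yaw_freq: float = 0.833  # Hz
    base_height: float = 1.0  # m

    @classmethod
    def none(cls) -> "PelvisMotion":
        return cls(0.0, 0, 0.0, 0, 0.0, 0, 0.0, 0, 0.0, 0, 1.0)

    @classmethod
    def walking(cls, cadence: float) -> "PelvisMotion":
        # amplitudes follow typical treadmill gait: ~4 deg pelvic obliquity,
        # ~2 deg tilt, ~5 deg zero-mean axial rotation, cm-scale translation
        fc = cadence / 120.0
        return cls(
            vertical_amp=0.02, vertical_freq=2 * fc,
            lateral_amp=0.025, lateral_freq=fc,
            roll_amp=4.0, roll_freq=fc,
            pitch_amp=2.0, pitch_freq=2 * fc,
            yaw_amp=5.0, yaw_freq=fc,
        )

    @classmethod
    def calibration(cls) -> "PelvisMotion":
        return cls(
            vertical_amp=0.05, vertical_freq=0.23,
            lateral_amp=0.06, lateral_freq=0.17,
            roll_amp=20.0, roll_freq=0.17,
            pitch_amp=20.0, pitch_freq=0.23,
            yaw_amp=25.0, yaw_freq=0.13,
        )


@dataclass
class NoiseSpec:
    """Sensor error model: white noise RMS and one constant bias per sensor.

    Defaults match the noisy study condition (gyro 0.01 rad/s RMS, accel
    0.1 m/s^2 RMS) with small constant biases.
    """

    gyro_rms: float = 0.01  # rad/s per axis
    accel_rms: float = 0.1  # m/s^2 per axis
    gyro_bias: float = 0.002  # rad/s per axis (std of the constant bias draw)
    accel_bias: float = 0.02  # m/s^2 per axis
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.gyro_rms, self.accel_rms, self.gyro_bias, self.accel_bias) < 0:
            raise ArgumentError("noise magnitudes must be nonnegative")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(0.0, 0.0, 0.0, 0.0, 0)


@dataclass
class SoftTissueSpec:
    """Gait-phase-locked mount perturbation about each segment's flexion axis.

    ``stance_deg`` / ``swing_deg`` are the knee-angle-equivalent perturbation
    levels; they are split between the thigh (-1/2) and shank (+1/2) sensors
    so the induced knee-angle error equals the stated level.  The perturbation
    varies C^1-smoothly with cycle phase (smoothstep transitions of width
    ``transition`` cycle fractions around toe off and heel strike).
    """

    stance_deg: float = 3.0
    swing_deg: float = -2.0
    transition: float = 0.05

    def __post_init__(self) -> None:
        if max(abs(self.stance_deg), abs(self.swing_deg)) > 30.0:
            raise ArgumentError("soft-tissue perturbation above 30 deg is nonphysical")
        if not 0.0 < self.transition < 0.2:
            raise ArgumentError("transition width must be in (0, 0.2) cycle fractions")


@dataclass
class SyntheticTrial:
    """Simulated recordings plus every ground-truth quantity needed to close
    the loop: angles, sensor state trajectories, static calibration, events."""

    array: SensorArray
    truth_angles: JointAngleProfiles
    truth_calibration: CalibrationParameters
    truth_states: dict[str, dict[str, np.ndarray]]  # sensor -> {R,p,v}
    mounts: MountSpec
    skeleton: SkeletonModel
    events: dict[str, np.ndarray]  # toe_off_r/l, heel_strike_r/l (s)
    seed: int
    fs: float
    kind: str
    noise: NoiseSpec = field(default_factory=NoiseSpec.zero)


# ---------------------------------------------------------------------------
# angle profiles
# ---------------------------------------------------------------------------


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def knee_waveform(phase: np.ndarray, amplitude_scale: float = 1.0) -> np.ndarray:
    """Two-peak knee flexion (deg) over cycle phase; maximum at phase 0."""
    c0, c1, c2, c3 = _KNEE_C
    w = (
        c0
        + c1 * np.cos(2 * np.pi * phase)
        + c2 * np.cos(4 * np.pi * phase)
        + c3 * np.cos(6 * np.pi * phase)
    )
    return amplitude_scale * w


def gait_profile(
    duration: float,
    fs: float,
    cadence: float = 100.0,
    hip_fe_amp: float = 18.0,
    hip_aa_amp: float = 4.0,
    hip_ie_amp: float = 3.0,
    ankle_amp: float = 8.0,
    degenerate_1dof: bool = False,
) -> JointAngleProfiles:
    """Periodic walking kinematics with antiphase left/right legs.

    The right leg's cycle phase is ``(t - T/4)/T`` so that knee-max-flexion
    events fall strictly inside the recording for both legs.  With
    ``degenerate_1dof`` the hip ab/adduction and internal/external channels
    are identically zero (the 1-DOF gait technique that makes the hip-center
    medial/lateral placement non-identifiable).
    """
    if duration <= 0 or fs <= 0 or cadence <= 0:
        raise ArgumentError("duration, fs and cadence must be positive")
    if min(hip_fe_amp, hip_aa_amp, hip_ie_amp, ankle_amp) < 0:
        raise ArgumentError("amplitudes must be nonnegative")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    T = 120.0 / cadence
    phases = {"r": (t - 0.25 * T) / T, "l": (t + 0.25 * T) / T}

    angles: dict[str, np.ndarray] = {}
    for side, ph in phases.items():
        two_pi = 2 * np.pi * ph
        fe = -8.0 + hip_fe_amp * np.cos(two_pi - 2 * np.pi * 0.45)
        aa = (0.0 if degenerate_1dof else 1.0) * hip_aa_amp * np.sin(two_pi + 0.4)
        ie = (0.0 if degenerate_1dof else 1.0) * hip_ie_amp * np.sin(two_pi + 1.1)
        knee = knee_waveform(ph)
        ankle = ankle_amp * np.sin(two_pi + 0.9)
        angles[f"hip_{side}"] = np.column_stack([fe, aa, ie])
        angles[f"knee_{side}"] = np.column_stack([knee, np.zeros(n), np.zeros(n)])
        angles[f"ankle_{side}"] = np.column_stack([ankle, np.zeros(n), np.zeros(n)])
    return JointAngleProfiles(t=t, angles=angles, cadence=cadence)


def gait_events(duration: float, cadence: float) -> dict[str, np.ndarray]:
    """Truth toe-off (knee max flexion) and heel-strike times, per side."""
    T = 120.0 / cadence
    events = {}
    for side, offset in (("r", 0.25 * T), ("l", 0.75 * T)):
        toe_off = np.arange(offset, duration, T)
        heel = toe_off + SWING_FRACTION * T
        events[f"toe_off_{side}"] = toe_off
        events[f"heel_strike_{side}"] = heel[heel < duration]
    return events


def calibration_profile(duration: float = 60.0, fs: float = 200.0) -> JointAngleProfiles:
    """A slow 3-DOF hip-exciting motion with deep knee flexion.

    Multi-frequency sinusoids (hip 0.20/0.13/0.17 Hz, knee 0.25 Hz, ankle
    0.21 Hz) under a 2 s smoothstep ramp-in so the trial starts at rest.
    Every hip channel sweeps >= 30 deg peak-to-peak and the knee flexes
    through >= 60 deg.  The knee and ankle carry a small (1 deg) non-hinge
    wobble: a real functional calibration is never a perfect hinge motion,
    and the wobble is what makes the along-axis component of the hinge-joint
    center vectors observable.
    """
    if duration < 10.0:
        raise ArgumentError("calibration profile must last at least 10 s")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    env = _smoothstep(t / 2.0)
    angles: dict[str, np.ndarray] = {}
    for side, ph0 in (("r", 0.0), ("l", 0.7)):
        fe = 28.0 * np.sin(2 * np.pi * 0.20 * t + ph0) * env
        aa = 20.0 * np.sin(2 * np.pi * 0.13 * t + 0.5 + ph0) * env
        ie = 20.0 * np.sin(2 * np.pi * 0.17 * t + 1.0 + ph0) * env
        knee = (35.0 - 35.0 * np.cos(2 * np.pi * 0.25 * t + ph0)) * env
        wob1 = 1.0 * np.sin(2 * np.pi * 0.19 * t + 0.8 + ph0) * env
        wob2 = 1.0 * np.sin(2 * np.pi * 0.23 * t + 1.7 + ph0) * env
        ankle = 12.0 * np.sin(2 * np.pi * 0.21 * t + 0.3 + ph0) * env
        wob3 = 1.0 * np.sin(2 * np.pi * 0.16 * t + 0.2 + ph0) * env
        wob4 = 1.0 * np.sin(2 * np.pi * 0.27 * t + 1.1 + ph0) * env
        angles[f"hip_{side}"] = np.column_stack([fe, aa, ie])
        angles[f"knee_{side}"] = np.column_stack([knee, wob1, wob2])
        angles[f"ankle_{side}"] = np.column_stack([ankle, wob3, wob4])
    return JointAngleProfiles(t=t, angles=angles, cadence=0.0)


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------


def _joint_rotation(angles_deg: np.ndarray, side: str) -> np.ndarray:
    """Rotation matrices for a 3-channel joint angle block (N, 3).

    Intrinsic x-y-z composition (the joint coordinate system with e1 = x of
    the proximal frame and e3 = z of the distal frame); ab/adduction and
    internal/external are sign-mirrored for the left side so that positive
    means adduction/internal bilaterally.
    """
    sgn = 1.0 if side == "r" else -1.0
    a = np.deg2rad(angles_deg) * np.array([1.0, sgn, sgn])
    return Rotation.from_euler("XYZ", a).as_matrix()


def forward_kinematics(
    profiles: JointAngleProfiles,
    skeleton: SkeletonModel | None = None,
    pelvis_motion: PelvisMotion | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """World pose (R (N,3,3), origin p (N,3)) of every segment.

    Segment origins are the proximal joint centers (pelvis: mid-hip point), so
    joint coincidence between adjacent segments is exact by construction.
    """
    skeleton = skeleton or SkeletonModel()
    pm = pelvis_motion or PelvisMotion.none()
    t = profiles.t
    n = t.shape[0]

    # smoothstep ramp keeps non-periodic (calibration) trials at rest at t=0
    env = 1.0 if profiles.cadence > 0 else _smoothstep(t / 2.0)
    p_pelvis = np.column_stack(
        [
            np.zeros(n),
            env * pm.lateral_amp * np.sin(2 * np.pi * pm.lateral_freq * t),
            pm.base_height
            + env * pm.vertical_amp * np.sin(2 * np.pi * pm.vertical_freq * t),
        ]
    )
    eul = np.column_stack(
        [
            np.deg2rad(pm.roll_amp) * np.sin(2 * np.pi * pm.roll_freq * t + 0.3),
            np.deg2rad(pm.pitch_amp) * np.sin(2 * np.pi * pm.pitch_freq * t + 0.8),
            np.deg2rad(pm.yaw_amp) * np.sin(2 * np.pi * pm.yaw_freq * t + 1.5),
        ]
    ) * (env if np.isscalar(env) else env[:, None])
    R_pelvis = Rotation.from_euler("xyz", eul).as_matrix()

    poses = {"pelvis": (R_pelvis, p_pelvis)}
    down_t = np.array([0.0, 0.0, -skeleton.thigh_length])
    down_s = np.array([0.0, 0.0, -skeleton.shank_length])
    for side, sx in (("r", 1.0), ("l", -1.0)):
        hip_local = np.array([sx * skeleton.pelvis_width / 2.0, 0.0, 0.0])
        p_hip = p_pelvis + R_pelvis @ hip_local
        R_thigh = R_pelvis @ _joint_rotation(profiles.angles[f"hip_{side}"], side)
        p_knee = p_hip + R_thigh @ down_t
        R_shank = R_thigh @ _joint_rotation(profiles.angles[f"knee_{side}"], side)
        p_ankle = p_knee + R_shank @ down_s
        R_foot = R_shank @ _joint_rotation(profiles.angles[f"ankle_{side}"], side)
        poses[f"thigh_{side}"] = (R_thigh, p_hip)
        poses[f"shank_{side}"] = (R_shank, p_knee)
        poses[f"foot_{side}"] = (R_foot, p_ankle)
    return poses


def joint_center_world(
    poses: dict[str, tuple[np.ndarray, np.ndarray]],
    skeleton: SkeletonModel,
    joint: str,
    from_side: str = "proximal",
) -> np.ndarray:
    """World trajectory of a joint center computed from either adjacent segment."""
    side = joint[-1]
    kind = joint[:-2]
    if kind == "hip":
        if from_side == "proximal":
            R, p = poses["pelvis"]
            sx = 1.0 if side == "r" else -1.0
            return p + R @ np.array([sx * skeleton.pelvis_width / 2.0, 0.0, 0.0])
        return poses[f"thigh_{side}"][1]
    if kind == "knee":
        if from_side == "proximal":
            R, p = poses[f"thigh_{side}"]
            return p + R @ np.array([0.0, 0.0, -skeleton.thigh_length])
        return poses[f"shank_{side}"][1]
    if kind == "ankle":
        if from_side == "proximal":
            R, p = poses[f"shank_{side}"]
            return p + R @ np.array([0.0, 0.0, -skeleton.shank_length])
        return poses[f"foot_{side}"][1]
    raise ArgumentError(f"unknown joint {joint}")


# ---------------------------------------------------------------------------
# inverse sensor model
# ---------------------------------------------------------------------------


def sensor_poses(
    segment_poses: dict[str, tuple[np.ndarray, np.ndarray]],
    mounts: MountSpec,
    mount_perturbation: dict[str, np.ndarray] | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sensor world pose series from segment poses and (possibly perturbed)
    mounts.  ``mount_perturbation[sid]`` is an (N, 3) rotvec series applied on
    the sensor side of the mount (soft-tissue motion of the skin patch)."""
    out = {}
    for sid in PLACEMENTS:
        seg = SEGMENT_OF_SENSOR[sid]
        R_seg, p_seg = segment_poses[seg]
        R_sm = mounts.rotations[sid]
        lever = mounts.levers[sid]
        R_ws = R_seg @ R_sm
        if mount_perturbation and sid in mount_perturbation:
            R_ws = R_ws @ expm(mount_perturbation[sid])
        p_ws = p_seg + R_seg @ lever
        out[sid] = (R_ws, p_ws)
    return out


def _discrete_velocity(p: np.ndarray, dt: float) -> np.ndarray:
    """Velocity sequence making the discrete strapdown recursion exact.

    Solves p_{k+1} = p_k + v_k dt + 0.5 u_k dt^2 with u_k = (v_{k+1}-v_k)/dt,
    i.e. v_{k+1} = 2 (p_{k+1}-p_k)/dt - v_k, with the marginally-stable
    alternating mode of the recursion removed against a central-difference
    reference.
    """
    n = p.shape[0]
    dpd = np.diff(p, axis=0) / dt  # (n-1, 3)
    v_c = np.empty_like(p)
    v_c[1:-1] = (p[2:] - p[:-2]) / (2 * dt)
    v_c[0] = (-3 * p[0] + 4 * p[1] - p[2]) / (2 * dt)
    v_c[-1] = (3 * p[-1] - 4 * p[-2] + p[-3]) / (2 * dt)

    def run(v0: np.ndarray) -> np.ndarray:
        v = np.empty_like(p)
        v[0] = v0
        # closed form of v_k = 2*dpd_{k-1} - v_{k-1}:
        #   v_k = (-1)^k v0 + 2 * sum_{j<k} (-1)^(k-1-j) dpd_j
        sj = (-1.0) ** np.arange(n - 1)
        csum = np.cumsum(dpd * sj[:, None], axis=0)
        k = np.arange(1, n)
        v[1:] = ((-1.0) ** k)[:, None] * v0 - 2.0 * ((-1.0) ** k)[:, None] * csum
        return v

    v = run(v_c[0])
    d = v - v_c
    alt = ((-1.0) ** np.arange(n))[:, None]
    corr = np.mean(alt * d, axis=0)
    return run(v_c[0] - corr)


def synthesize_imu(
    sensor_pose_series: dict[str, tuple[np.ndarray, np.ndarray]],
    fs: float,
    noise: NoiseSpec | None = None,
) -> tuple[SensorArray, dict[str, dict[str, np.ndarray]]]:
    """Simulate gyro/accel streams from sensor pose series.

    Returns the (possibly noisy) :class:`SensorArray` and the noise-free truth
    states per sensor (orientation matrices R, world positions p and the
    discrete-consistent world velocities v).
    """
    noise = noise or NoiseSpec.zero()
    dt = 1.0 / fs
    rng = np.random.default_rng(noise.seed)
    recs = []
    truth: dict[str, dict[str, np.ndarray]] = {}
    for sid in PLACEMENTS:
        R, p = sensor_pose_series[sid]
        n = R.shape[0]
        t = np.arange(n) * dt
        gyro = np.empty((n, 3))
        gyro[:-1] = logm(np.swapaxes(R[:-1], -1, -2) @ R[1:]) / dt
        gyro[-1] = gyro[-2]
        v = _discrete_velocity(p, dt)
        u = np.empty_like(p)  # world acceleration consistent with v
        u[:-1] = np.diff(v, axis=0) / dt
        u[-1] = u[-2]
        accel = np.einsum("nij,nj->ni", np.swapaxes(R, -1, -2), u - GRAVITY)
        truth[sid] = {"R": R, "p": p, "v": v}
        g_noisy = gyro + rng.normal(0.0, noise.gyro_bias, 3) + rng.normal(
            0.0, noise.gyro_rms, (n, 3)
        ) * (noise.gyro_rms > 0)
        a_noisy = accel + rng.normal(0.0, noise.accel_bias, 3) + rng.normal(
            0.0, noise.accel_rms, (n, 3)
        ) * (noise.accel_rms > 0)
        recs.append(ImuRecording(sensor_id=sid, t=t, gyro=g_noisy, accel=a_noisy, fs=fs))
    return assemble_array(recs), truth


# ---------------------------------------------------------------------------
# truth calibration bookkeeping
# ---------------------------------------------------------------------------


def truth_calibration(skeleton: SkeletonModel, mounts: MountSpec) -> CalibrationParameters:
    """Exact joint-center vectors and hinge axes implied by the mount geometry."""
    joint_in_segment = {}
    for side, sx in (("r", 1.0), ("l", -1.0)):
        joint_in_segment[("pelvis", f"hip_{side}")] = np.array(
            [sx * skeleton.pelvis_width / 2.0, 0.0, 0.0]
        )
        joint_in_segment[(f"thigh_{side}", f"hip_{side}")] = np.zeros(3)
        joint_in_segment[(f"thigh_{side}", f"knee_{side}")] = np.array(
            [0.0, 0.0, -skeleton.thigh_length]
        )
        joint_in_segment[(f"shank_{side}", f"knee_{side}")] = np.zeros(3)
        joint_in_segment[(f"shank_{side}", f"ankle_{side}")] = np.array(
            [0.0, 0.0, -skeleton.shank_length]
        )
        joint_in_segment[(f"foot_{side}", f"ankle_{side}")] = np.zeros(3)

    jc = {}
    axes = {}
    for joint, (prox, dist) in JOINT_PAIRS.items():
        for sid in (prox, dist):
            seg = SEGMENT_OF_SENSOR[sid]
            R_sm = mounts.rotations[sid]
            lever = mounts.levers[sid]
            jloc = joint_in_segment[(seg, joint)]
            jc[(sid, joint)] = R_sm.T @ (jloc - lever)
            # all hinge / pseudo-hinge axes are the segment's +x (flexion) axis
            axes[(sid, joint)] = R_sm.T @ np.array([1.0, 0.0, 0.0])
    return CalibrationParameters(jc=jc, axes=axes)


# ---------------------------------------------------------------------------
# soft tissue injection
# ---------------------------------------------------------------------------


def _phase_of(t: np.ndarray, toe_off: np.ndarray, period: float) -> np.ndarray:
    """Cycle phase in [0, 1) relative to the nearest preceding toe-off."""
    return ((t - toe_off[0]) / period) % 1.0


def soft_tissue_offset(phase: np.ndarray, spec: SoftTissueSpec) -> np.ndarray:
    """C^1 perturbation level (deg) as a function of cycle phase.

    Swing spans [0, SWING_FRACTION), stance the rest; smoothstep transitions
    of half-width ``spec.transition`` are centered on the two boundaries.
    """
    w = spec.transition
    lo, hi = spec.swing_deg, spec.stance_deg
    # transition swing->stance centered at SWING_FRACTION, stance->swing at 1.0
    up = _smoothstep((phase - (SWING_FRACTION - w)) / (2 * w))
    down = _smoothstep((phase - (1.0 - w)) / (2 * w))
    val = lo + (hi - lo) * up - (hi - lo) * down
    # wrap: just before phase 0 the down-transition has begun; just after 0 it
    # must complete from the stance level
    tail = _smoothstep((phase + w) / (2 * w))
    val = val + (hi - lo) * (1.0 - tail)
    return val


def inject_soft_tissue(trial: "SyntheticTrial", spec: SoftTissueSpec) -> "SyntheticTrial":
    """Regenerate thigh/shank signals with phase-locked mount perturbations.

    The perturbation rotates each thigh sensor by ``-offset/2`` and each shank
    sensor by ``+offset/2`` about the segment's flexion axis (expressed in the
    sensor frame via the truth calibration), so the knee-angle-equivalent
    perturbation equals the stated levels.  Ground truth (states, angles,
    calibration) is left at the skin-free skeleton values — that mismatch *is*
    the artifact under study.
    """
    if trial.truth_angles.cadence == 0:
        raise ArgumentError("soft-tissue injection requires a gait trial with events")
    t = trial.array.t
    period = trial.truth_angles.cycle_period
    pert: dict[str, np.ndarray] = {}
    for side in ("r", "l"):
        phase = _phase_of(t, trial.events[f"toe_off_{side}"], period)
        offset = np.deg2rad(soft_tissue_offset(phase, spec))
        for sid, gain in ((f"thigh_{side}", -0.5), (f"shank_{side}", +0.5)):
            axis = trial.truth_calibration.axes[(sid, f"knee_{side}")]
            pert[sid] = (gain * offset)[:, None] * axis[None, :]
    base_poses = {sid: (st["R"], st["p"]) for sid, st in trial.truth_states.items()}
    perturbed = {
        sid: ((R @ expm(pert[sid])) if sid in pert else R, p)
        for sid, (R, p) in base_poses.items()
    }
    array, _ = synthesize_imu(perturbed, trial.fs, trial.noise)
    return replace(trial, array=array)


def truth_estimate(trial: "SyntheticTrial", problem, start_sample: int = 0):
    """Pack the trial's ground truth into an estimator iterate.

    Used by closed-loop oracles: at this estimate every inertial,
    joint-center and (for hinge-consistent motion) hinge residual of a
    noise-free trial vanishes to round-off.
    """
    from .calibration import AXIS_KEYS as AK, JC_KEYS as JK
    from .estimator import Estimate

    K, M = problem.K, problem.M
    idx = start_sample + np.arange(K) * M
    R = np.stack([trial.truth_states[sid]["R"][idx] for sid in PLACEMENTS])
    v = np.stack([trial.truth_states[sid]["v"][idx] for sid in PLACEMENTS])
    p = np.stack([trial.truth_states[sid]["p"][idx] for sid in PLACEMENTS])
    jc = np.stack([trial.truth_calibration.jc[k] for k in JK])
    axes = np.stack([trial.truth_calibration.axes[k] for k in AK])
    return Estimate(
        R=R, v=v, p=p,
        bg=np.zeros((len(PLACEMENTS), 3)), ba=np.zeros((len(PLACEMENTS), 3)),
        jc=jc, axes=axes,
    )


def truth_solution(trial: "SyntheticTrial", keyframe_rate: float = 20.0):
    """Package the trial's ground truth as a converged-looking Solution.

    Lets the angle-derivation and drift modules be exercised closed-loop
    without running the optimizer.
    """
    from .estimator import Solution, StateTrajectory

    fs = trial.fs
    M = int(round(fs / keyframe_rate))
    n = trial.array.n_samples
    idx = np.arange(0, n, M)
    trajs = {}
    for sid in PLACEMENTS:
        st = trial.truth_states[sid]
        trajs[sid] = StateTrajectory(
            sensor_id=sid,
            times=trial.array.t[idx],
            R=st["R"][idx].copy(),
            v=st["v"][idx].copy(),
            p=st["p"][idx].copy(),
        )
    return Solution(
        trajectories=trajs,
        calibration=trial.truth_calibration,
        cost=0.0,
        convergence="absolute",
        iterations=0,
    )


# ---------------------------------------------------------------------------
# trial factory
# ---------------------------------------------------------------------------


def generate_trial(
    kind: str,
    seed: int = 0,
    duration: float | None = None,
    fs: float = 200.0,
    cadence: float = 100.0,
    degenerate_1dof: bool = False,
    noise: NoiseSpec | None = None,
    skeleton: SkeletonModel | None = None,
    mounts: MountSpec | None = None,
    randomize_mounts: bool = False,
    soft_tissue: SoftTissueSpec | None = None,
    pelvis_motion: PelvisMotion | None = None,
) -> SyntheticTrial:
    """Bundle profiles -> forward kinematics -> IMU synthesis into a trial.

    ``kind`` is ``"walking"`` or ``"calibration"``.  With a fixed seed the
    trial is bit-reproducible.  ``noise=None`` means noise-free.
    """
    if kind not in ("walking", "calibration"):
        raise ArgumentError(f"unknown trial kind {kind!r}")
    skeleton = skeleton or SkeletonModel()
    mounts = mounts or (default_mounts(seed) if randomize_mounts else default_mounts())
    noise_spec = noise if noise is not None else NoiseSpec.zero()
    noise_spec = replace(noise_spec, seed=noise_spec.seed + seed)

    if kind == "walking":
        duration = 30.0 if duration is None else duration
        profiles = gait_profile(duration, fs, cadence=cadence, degenerate_1dof=degenerate_1dof)
        pm = pelvis_motion if pelvis_motion is not None else PelvisMotion.walking(cadence)
        events = gait_events(duration, cadence)
    else:
        duration = 60.0 if duration is None else duration
        profiles = calibration_profile(duration, fs)
        pm = pelvis_motion if pelvis_motion is not None else PelvisMotion.calibration()
        events = {}

    seg_poses = forward_kinematics(profiles, skeleton, pm)
    sposes = sensor_poses(seg_poses, mounts)
    array, truth_states = synthesize_imu(sposes, fs, noise_spec)
    calib = truth_calibration(skeleton, mounts)
    trial = SyntheticTrial(
        array=array,
        truth_angles=profiles,
        truth_calibration=calib,
        truth_states=truth_states,
        mounts=mounts,
        skeleton=skeleton,
        events=events,
        seed=seed,
        fs=fs,
        kind=kind,
        noise=noise_spec,
    )
    if soft_tissue is not None:
        trial = inject_soft_tissue(trial, soft_tissue)
    return trial
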