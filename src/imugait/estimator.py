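"""Joint estimation of per-IMU pose trajectories and static sensor-to-joint
calibration by sparse nonlinear least squares.

The unknowns of one window are, per sensor, a keyframe-rate trajectory of
orientation / velocity / position plus one constant gyro and accelerometer
bias, and, shared across sensors, the static calibration: twelve
joint-center vectors and twelve hinge-axis directions in sensor frames.

Residual families
-----------------
inertial
    Preintegrated strapdown constraints between consecutive keyframes: the
    bias-corrected gyro/accel samples of the interval, integrated, must carry
    state k into state k+1 under gravity.
joint center
    The two sensors flanking each joint, each offset by its static
    joint-center vector, must place the joint at the same world point at
    every keyframe.
hinge
    The two sensors flanking each joint must agree on the world direction of
    the joint's hinge axis.  The knee is a tight hinge; hip and ankle are
    "noisy" hinges with a much larger tolerance — they admit non-hinge motion
    but pin the otherwise non-identifiable relative heading between the
    flanking sensors.
priors
    Gaussian priors on the four hip-connected joint-center vectors (from the
    calibration task; mandatory for pure walking, where 1-DOF hip kinematics
    make the medial/lateral hip-center placement non-identifiable), gauge
    priors (first-keyframe lumbar position, heading and velocity), weak
    zero-mean bias priors, and unit-norm residuals for the axis unknowns.

The solver is Levenberg-Marquardt on the stacked whitened residual with
analytic sparse Jacobians; it terminates on an absolute cost change of 1e-6
or less, a relative cost change of 1e-4 or less, or 10,000 iterations,
whichever comes first, and records which criterion fired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._so3 import expm, hat, logm, right_jacobian, right_jacobian_inv, yaw_of
from .calibration import (
    AXIS_KEYS,
    HIP_JC_KEYS,
    JC_KEYS,
    JOINT_PAIRS,
    JOINTS,
    CalibrationParameters,
    Priors,
)
from .errors import ArgumentError, InitializationError
from .io import PLACEMENTS, SensorArray

logger = logging.getLogger("imugait")

GRAVITY = np.array([0.0, 0.0, -9.81])

_ABS_TOL = 1e-6  # absolute cost-change convergence threshold
_REL_TOL = 1e-4  # relative cost-change convergence threshold
_MAX_ITERS = 10_000


@dataclass
class NoiseConfig:
    """Residual weighting (1-sigma) for the estimation problem.

    The hinge sigmas are in radians of axis misalignment; the knee must be
    tighter than the hip and ankle pseudo-hinges (the latter are deliberately
    loose so non-hinge motion is permitted).
    """

    sigma_gyro: float = 0.01  # rad/s
    sigma_accel: float = 0.1  # m/s^2
    sigma_jc: float = 0.005  # m
    sigma_hinge_knee: float = 0.05  # rad
    sigma_hinge_hip: float = 0.3  # rad
    sigma_hinge_ankle: float = 0.3  # rad
    sigma_bias_gyro: float = 0.02  # rad/s, zero-mean prior on constant bias
    sigma_bias_accel: float = 0.2  # m/s^2
    sigma_gauge_pos: float = 1e-4  # m
    sigma_gauge_vel: float = 1e-4  # m/s
    sigma_gauge_yaw: float = 1e-4  # rad
    sigma_axis_norm: float = 1e-3  # unit-norm constraint weight
    sigma_jc_reg: float = 0.1  # m, zero-mean prior on non-hip joint-center
    # vectors: bounds their flat along-hinge-axis direction (pure hinge
    # motion cannot observe it; joint angles are invariant to it).  The four
    # hip-connected vectors are deliberately NOT regularized — their
    # medial/lateral non-identifiability under 1-DOF gait is a property of
    # the model, handled by calibration-task priors instead.
    gravity: float = 9.81

    def __post_init__(self) -> None:
        vals = [
            self.sigma_gyro, self.sigma_accel, self.sigma_jc,
            self.sigma_hinge_knee, self.sigma_hinge_hip, self.sigma_hinge_ankle,
            self.sigma_bias_gyro, self.sigma_bias_accel,
        ]
        if min(vals) <= 0:
            raise ArgumentError("all sigmas must be positive")
        if not (self.sigma_hinge_knee < self.sigma_hinge_hip
                and self.sigma_hinge_knee < self.sigma_hinge_ankle):
            raise ArgumentError("knee hinge must be tighter than hip and ankle")

    def hinge_sigma(self, joint: str) -> float:
        kind = joint[:-2]
        return {
            "knee": self.sigma_hinge_knee,
            "hip": self.sigma_hinge_hip,
            "ankle": self.sigma_hinge_ankle,
        }[kind]


@dataclass
class ImuState:
    """One sensor's state at a keyframe: R maps sensor to world coordinates."""

    R: np.ndarray
    p: np.ndarray = field(default_factory=lambda: np.zeros(3))
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ba: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class StateTrajectory:
    """Keyframe-rate state time series of one sensor."""

    sensor_id: str
    times: np.ndarray
    R: np.ndarray  # (K, 3, 3), sensor -> world
    v: np.ndarray  # (K, 3), world
    p: np.ndarray  # (K, 3), world
    bg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ba: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class Estimate:
    """Packed iterate of one window: stacked over sensors in PLACEMENTS order."""

    R: np.ndarray  # (S, K, 3, 3)
    v: np.ndarray  # (S, K, 3)
    p: np.ndarray  # (S, K, 3)
    bg: np.ndarray  # (S, 3)
    ba: np.ndarray  # (S, 3)
    jc: np.ndarray  # (12, 3), JC_KEYS order
    axes: np.ndarray  # (12, 3), AXIS_KEYS order

    def copy(self) -> "Estimate":
        return Estimate(
            self.R.copy(), self.v.copy(), self.p.copy(),
            self.bg.copy(), self.ba.copy(), self.jc.copy(), self.axes.copy(),
        )


@dataclass
class Solution:
    """Converged window solution."""

    trajectories: dict[str, StateTrajectory]
    calibration: CalibrationParameters
    cost: float
    convergence: str  # 'absolute' | 'relative' | 'max_iterations'
    iterations: int
    estimate: Estimate = field(repr=False, default=None)
    problem: "EstimationProblem" = field(repr=False, default=None)


@dataclass
class WalkingSolution:
    """Per-window solutions of a windowed walking trial, in time order."""

    windows: list[Solution]
    window_start_times: list[float]


# ---------------------------------------------------------------------------
# spec-level residual primitives (single-evaluation reference forms)
# ---------------------------------------------------------------------------


def residual_joint_center(
    stateA: ImuState, stateB: ImuState, sA: np.ndarray, sB: np.ndarray
) -> np.ndarray:
    """Disagreement (m, world) of the joint-center point predicted by the two
    flanking sensors: r = (pA + R_A sA) - (pB + R_B sB)."""
    return (stateA.p + stateA.R @ np.asarray(sA, float)) - (
        stateB.p + stateB.R @ np.asarray(sB, float)
    )


def residual_hinge(
    stateA: ImuState, stateB: ImuState, aA: np.ndarray, aB: np.ndarray
) -> np.ndarray:
    """World-frame hinge-axis disagreement r = R_A aA - R_B aB (unit axes)."""
    aA = np.asarray(aA, float)
    aB = np.asarray(aB, float)
    if abs(np.linalg.norm(aA) - 1) > 1e-6 or abs(np.linalg.norm(aB) - 1) > 1e-6:
        raise ArgumentError("hinge axes must be unit vectors")
    return stateA.R @ aA - stateB.R @ aB


def preintegrate(
    gyro: np.ndarray, accel: np.ndarray, dt: float,
    bg: np.ndarray, ba: np.ndarray,
) -> dict[str, np.ndarray]:
    """Integrate bias-corrected samples over intervals (batched).

    ``gyro``/``accel`` have shape (..., M, 3).  Returns DR, Dv, Dp and the
    first-order Jacobians of each with respect to the gyro/accel biases.
    """
    w = gyro - bg[..., None, :]
    a = accel - ba[..., None, :]
    lead = w.shape[:-2]
    M = w.shape[-2]
    DR = np.broadcast_to(np.eye(3), lead + (3, 3)).copy()
    Dv = np.zeros(lead + (3,))
    Dp = np.zeros(lead + (3,))
    JRg = np.zeros(lead + (3, 3))
    Jvg = np.zeros(lead + (3, 3))
    Jva = np.zeros(lead + (3, 3))
    Jpg = np.zeros(lead + (3, 3))
    Jpa = np.zeros(lead + (3, 3))
    for m in range(M):
        wm = w[..., m, :]
        am = a[..., m, :]
        E = expm(wm * dt)
        Ha = hat(am)
        Jpg = Jpg + Jvg * dt - 0.5 * dt * dt * (DR @ Ha @ JRg)
        Jpa = Jpa + Jva * dt - 0.5 * dt * dt * DR
        Jvg = Jvg - dt * (DR @ Ha @ JRg)
        Jva = Jva - dt * DR
        JRg = np.swapaxes(E, -1, -2) @ JRg - right_jacobian(wm * dt) * dt
        Dp = Dp + Dv * dt + 0.5 * dt * dt * np.einsum("...ij,...j->...i", DR, am)
        Dv = Dv + dt * np.einsum("...ij,...j->...i", DR, am)
        DR = DR @ E
    return {"DR": DR, "Dv": Dv, "Dp": Dp,
            "JRg": JRg, "Jvg": Jvg, "Jva": Jva, "Jpg": Jpg, "Jpa": Jpa}


def residual_inertial(
    state_i: ImuState, state_j: ImuState,
    gyro: np.ndarray, accel: np.ndarray, dt: float,
    cfg: NoiseConfig,
) -> np.ndarray:
    """Whitened 9-vector (rotation, velocity, position) preintegration error
    between two keyframe states bridged by the given samples."""
    pre = preintegrate(np.asarray(gyro, float), np.asarray(accel, float), dt,
                       state_i.bg, state_i.ba)
    Dt = gyro.shape[0] * dt
    g = np.array([0.0, 0.0, -cfg.gravity])
    rR = logm(pre["DR"].T @ state_i.R.T @ state_j.R)
    rv = state_i.R.T @ (state_j.v - state_i.v - g * Dt) - pre["Dv"]
    rp = state_i.R.T @ (
        state_j.p - state_i.p - state_i.v * Dt - 0.5 * g * Dt * Dt
    ) - pre["Dp"]
    s_r = cfg.sigma_gyro * np.sqrt(Dt * dt)
    s_v = cfg.sigma_accel * np.sqrt(Dt * dt)
    s_p = s_v * Dt
    return np.concatenate([rR / s_r, rv / s_v, rp / s_p])


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _cumulative_matmul(D: np.ndarray) -> np.ndarray:
    """Inclusive prefix product P_k = D_0 @ ... @ D_k via doubling scan."""
    P = D.copy()
    n = P.shape[0]
    o = 1
    while o < n:
        P[o:] = P[:-o] @ P[o:]
        o *= 2
    return P


def initialize_states(
    array: SensorArray, keyframe_rate: float = 20.0,
    leveling_window: float | None = None,
) -> dict[str, StateTrajectory]:
    """Initial guess: gravity leveling + gyro dead reckoning.

    Roll/pitch come from the mean specific force over the leveling window
    (heading set to zero); orientation is then dead-reckoned from the gyro
    at full rate and subsampled to keyframes.  Positions, velocities and
    biases start at zero.

    The default window is the whole recording: over cyclic motion the
    dynamic accelerations average out and the mean specific force points
    along gravity, whereas a short early window can be badly biased (a foot
    sensor mid-swing sees several m/s^2 of motion).  Pass an explicit window
    (e.g. 0.5 s) for recordings that start at rest.
    """
    if leveling_window is not None and array.duration < leveling_window:
        raise ArgumentError(f"need at least {leveling_window} s of data to level")
    if array.duration < 0.5:
        raise ArgumentError("need at least 0.5 s of data to level")
    dt = 1.0 / array.fs
    M = int(round(array.fs / keyframe_rate))
    if M < 1 or abs(array.fs / keyframe_rate - M) > 1e-9:
        raise ArgumentError("fs must be an integer multiple of keyframe_rate")
    if leveling_window is None:
        n_lvl = array.n_samples
    else:
        n_lvl = max(2, int(round(leveling_window * array.fs)))
    out: dict[str, StateTrajectory] = {}
    for sid in PLACEMENTS:
        rec = array[sid]
        # dead-reckon in an arbitrary start frame, then level: the mean
        # specific force expressed in that common frame points along the
        # (rotated) gravity direction once the dynamics average out
        incr = expm(rec.gyro[:-1] * dt)
        Rtilde = np.empty((rec.n_samples, 3, 3))
        Rtilde[0] = np.eye(3)
        Rtilde[1:] = _cumulative_matmul(incr)
        f = np.einsum("kij,kj->i", Rtilde[:n_lvl], rec.accel[:n_lvl]) / n_lvl
        fn = f / np.linalg.norm(f)
        # minimal rotation taking the measured up direction to world z, then
        # remove any residual heading so the convention is yaw = 0
        axis = np.cross(fn, [0.0, 0.0, 1.0])
        s = np.linalg.norm(axis)
        c = float(fn @ [0.0, 0.0, 1.0])
        if s < 1e-12:
            fix = np.eye(3) if c > 0 else expm(np.array([np.pi, 0, 0]))
        else:
            fix = expm(axis / s * np.arctan2(s, c))
        fix = expm(np.array([0.0, 0.0, -yaw_of(fix)])) @ fix
        Rfull = fix @ Rtilde
        K = (rec.n_samples - 1) // M + 1
        idx = np.arange(K) * M
        out[sid] = StateTrajectory(
            sensor_id=sid,
            times=rec.t[idx],
            R=Rfull[idx],
            v=np.zeros((K, 3)),
            p=np.zeros((K, 3)),
        )
    return out


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------

_SID_INDEX = {sid: i for i, sid in enumerate(PLACEMENTS)}
_JC_INDEX = {key: i for i, key in enumerate(JC_KEYS)}
_AXIS_INDEX = {key: i for i, key in enumerate(AXIS_KEYS)}


class EstimationProblem:
    """One window's residual system over states + calibration.

    Parameters
    ----------
    array : SensorArray
        The window's synchronized recordings.
    cfg : NoiseConfig
        Residual weights.
    keyframe_rate : float
        State rate (Hz); fs must be an integer multiple.
    priors : Priors or None
        Hip-connected joint-center priors.  A walking-kind problem without
        them is assembled but logged as an identifiability risk.
    kind : str
        'calibration' or 'walking' (affects only the warning above).
    hinge_joints : sequence of joint ids
        Joints that contribute hinge residuals (default: all six).
    """

    def __init__(
        self,
        array: SensorArray,
        cfg: NoiseConfig | None = None,
        keyframe_rate: float = 20.0,
        priors: Priors | None = None,
        kind: str = "calibration",
        hinge_joints: tuple[str, ...] = JOINTS,
    ) -> None:
        if array.n_samples < 2:
            raise ArgumentError("empty window")
        if kind not in ("calibration", "walking"):
            raise ArgumentError(f"unknown problem kind {kind!r}")
        if kind == "walking" and priors is None:
            logger.warning(
                "walking-kind problem assembled without hip-vector priors: "
                "medial/lateral hip-center placement may be non-identifiable"
            )
        self.array = array
        self.cfg = cfg or NoiseConfig()
        self.kind = kind
        self.priors = priors
        self.keyframe_rate = float(keyframe_rate)
        self.hinge_joints = tuple(hinge_joints)

        self.fs = array.fs
        self.dt = 1.0 / self.fs
        M = int(round(self.fs / keyframe_rate))
        if M < 1 or abs(self.fs / keyframe_rate - M) > 1e-9:
            raise ArgumentError("fs must be an integer multiple of keyframe_rate")
        self.M = M
        self.K = (array.n_samples - 1) // M + 1
        if self.K < 2:
            raise ArgumentError("window too short for one keyframe interval")
        self.Dt = M * self.dt
        self.S = len(PLACEMENTS)
        K, S = self.K, self.S

        # measurement tensors (S, K-1, M, 3)
        n_used = (K - 1) * M
        self.gyro = np.stack(
            [array[sid].gyro[:n_used].reshape(K - 1, M, 3) for sid in PLACEMENTS]
        )
        self.accel = np.stack(
            [array[sid].accel[:n_used].reshape(K - 1, M, 3) for sid in PLACEMENTS]
        )
        self.kf_times = array.t[np.arange(K) * M]

        # unknown layout: keyframe-major (all sensors' states at keyframe k
        # contiguous) so the normal equations are banded with a dense
        # bias/calibration border — natural-order LU then has minimal fill
        self.n_state = 9 * K * S
        self.bias0 = self.n_state
        self.calib0 = self.bias0 + 6 * S
        self.n_unknowns = self.calib0 + 36 + 36

        # gauge anchors, set on first solve from the initial estimate
        self.gauge: dict[str, np.ndarray | float] | None = None

        self._build_index_templates()

    # -- index helpers ----------------------------------------------------

    def _th(self, s: int, k) -> np.ndarray:
        return 9 * self.S * np.asarray(k) + 9 * s

    def _v(self, s: int, k) -> np.ndarray:
        return self._th(s, k) + 3

    def _p(self, s: int, k) -> np.ndarray:
        return self._th(s, k) + 6

    def _bg(self, s: int) -> int:
        return self.bias0 + 6 * s

    def _ba(self, s: int) -> int:
        return self.bias0 + 6 * s + 3

    def _jc(self, key) -> int:
        return self.calib0 + 3 * _JC_INDEX[key]

    def _axis(self, key) -> int:
        return self.calib0 + 36 + 3 * _AXIS_INDEX[key]

    def _build_index_templates(self) -> None:
        K, S = self.K, self.S
        kk = np.arange(K - 1)

        # inertial: (S, K-1) blocks of 9 rows x 24 cols
        cols = np.empty((S, K - 1, 24), dtype=np.int64)
        for s in range(S):
            base = np.stack(
                [self._th(s, kk), self._v(s, kk), self._p(s, kk),
                 self._th(s, kk + 1), self._v(s, kk + 1), self._p(s, kk + 1)],
                axis=-1,
            )  # (K-1, 6) leading col of each triplet
            trip = (base[..., None] + np.arange(3)).reshape(K - 1, 18)
            bias_cols = np.concatenate(
                [self._bg(s) + np.arange(3), self._ba(s) + np.arange(3)]
            )
            cols[s] = np.concatenate(
                [trip, np.broadcast_to(bias_cols, (K - 1, 6))], axis=-1
            )
        n_in = S * (K - 1) * 9
        rows = np.arange(n_in).reshape(S, K - 1, 9)
        self._in_rows = np.broadcast_to(rows[..., None], (S, K - 1, 9, 24)).ravel()
        self._in_cols = np.broadcast_to(cols[:, :, None, :], (S, K - 1, 9, 24)).ravel()
        row0 = n_in

        # joint center: per joint, K blocks of 3 rows x 18 cols
        kk_all = np.arange(K)
        jc_cols = np.empty((6, K, 18), dtype=np.int64)
        self._jc_meta = []
        for j, joint in enumerate(JOINTS):
            A, B = JOINT_PAIRS[joint]
            sA, sB = _SID_INDEX[A], _SID_INDEX[B]
            base = np.stack(
                [self._th(sA, kk_all), self._p(sA, kk_all),
                 self._th(sB, kk_all), self._p(sB, kk_all)],
                axis=-1,
            )
            trip = (base[..., None] + np.arange(3)).reshape(K, 12)
            cal = np.concatenate(
                [self._jc((A, joint)) + np.arange(3),
                 self._jc((B, joint)) + np.arange(3)]
            )
            jc_cols[j] = np.concatenate(
                [trip, np.broadcast_to(cal, (K, 6))], axis=-1
            )
            self._jc_meta.append((sA, sB, _JC_INDEX[(A, joint)], _JC_INDEX[(B, joint)]))
        n_jc = 6 * K * 3
        rows = row0 + np.arange(n_jc).reshape(6, K, 3)
        self._jc_rows = np.broadcast_to(rows[..., None], (6, K, 3, 18)).ravel()
        self._jc_cols = np.broadcast_to(jc_cols[:, :, None, :], (6, K, 3, 18)).ravel()
        row0 += n_jc

        # hinge: per enabled joint, K blocks of 3 rows x 12 cols
        self._hinge_meta = []
        h_cols_list = []
        for joint in self.hinge_joints:
            A, B = JOINT_PAIRS[joint]
            sA, sB = _SID_INDEX[A], _SID_INDEX[B]
            base = np.stack([self._th(sA, kk_all), self._th(sB, kk_all)], axis=-1)
            trip = (base[..., None] + np.arange(3)).reshape(K, 6)
            cal = np.concatenate(
                [self._axis((A, joint)) + np.arange(3),
                 self._axis((B, joint)) + np.arange(3)]
            )
            h_cols_list.append(
                np.concatenate([trip, np.broadcast_to(cal, (K, 6))], axis=-1)
            )
            self._hinge_meta.append(
                (sA, sB, _AXIS_INDEX[(A, joint)], _AXIS_INDEX[(B, joint)],
                 self.cfg.hinge_sigma(joint))
            )
        nh = len(self.hinge_joints)
        n_h = nh * K * 3
        if nh:
            h_cols = np.stack(h_cols_list)
            rows = row0 + np.arange(n_h).reshape(nh, K, 3)
            self._h_rows = np.broadcast_to(rows[..., None], (nh, K, 3, 12)).ravel()
            self._h_cols = np.broadcast_to(h_cols[:, :, None, :], (nh, K, 3, 12)).ravel()
        else:
            self._h_rows = np.empty(0, dtype=np.int64)
            self._h_cols = np.empty(0, dtype=np.int64)
        row0 += n_h

        # axis unit-norm: 12 rows x 3 cols
        rows = row0 + np.arange(12)
        cols = self.calib0 + 36 + (np.arange(12)[:, None] * 3 + np.arange(3))
        self._norm_rows = np.broadcast_to(rows[:, None], (12, 3)).ravel()
        self._norm_cols = cols.ravel()
        row0 += 12

        # priors: built per-solve (count is fixed)
        self._prior_row0 = row0
        n_prior = 6 * S  # bias priors
        n_prior += 7  # gauge: lumbar p0 (3), v0 (3), yaw0 (1)
        n_prior += 24  # zero-mean regularization of the 8 non-hip jc vectors
        if self.priors is not None:
            n_prior += 12
        self.n_residuals = row0 + n_prior

    def residual_blocks(self, est: "Estimate") -> dict[str, np.ndarray]:
        """Whitened residuals split by family (measurement families first)."""
        r = self.residuals(est)
        K, S = self.K, self.S
        n_in = S * (K - 1) * 9
        n_jc = 6 * K * 3
        n_h = len(self.hinge_joints) * K * 3
        return {
            "inertial": r[:n_in],
            "joint_center": r[n_in: n_in + n_jc],
            "hinge": r[n_in + n_jc: n_in + n_jc + n_h],
            "axis_norm": r[n_in + n_jc + n_h: n_in + n_jc + n_h + 12],
            "priors": r[n_in + n_jc + n_h + 12:],
        }

    # -- public counts -----------------------------------------------------

    def describe(self) -> dict[str, int]:
        K, S = self.K, self.S
        return {
            "n_unknowns": self.n_unknowns,
            "n_residuals": self.n_residuals,
            "n_keyframes": K,
            "inertial_intervals": S * (K - 1),
            "joint_center_blocks": 6 * K,
            "hinge_blocks": len(self.hinge_joints) * K,
        }

    # -- estimate handling -------------------------------------------------

    def initial_estimate(self) -> Estimate:
        trajs = initialize_states(self.array, self.keyframe_rate)
        R = np.stack([trajs[sid].R for sid in PLACEMENTS])
        K, S = self.K, self.S
        est = Estimate(
            R=R[:, :K],
            v=np.zeros((S, K, 3)),
            p=np.zeros((S, K, 3)),
            bg=np.zeros((S, 3)),
            ba=np.zeros((S, 3)),
            jc=np.zeros((12, 3)),
            axes=np.zeros((12, 3)),
        )
        # axis guesses: the world x-axis at the first keyframe mapped into
        # each sensor frame (standing subject, flexion axes near horizontal)
        for i, (sid, _joint) in enumerate(AXIS_KEYS):
            s = _SID_INDEX[sid]
            est.axes[i] = est.R[s, 0].T @ np.array([1.0, 0.0, 0.0])
        if self.priors is not None:
            for key in HIP_JC_KEYS:
                est.jc[_JC_INDEX[key]] = self.priors.hip_jc[key][0]
        return est

    def estimate_from_solution(self, sol: "Solution") -> Estimate:
        return sol.estimate.copy()

    def set_gauge_from(self, est: Estimate) -> None:
        s = _SID_INDEX["lumbar"]
        self.gauge = {
            "p0": est.p[s, 0].copy(),
            "v0": est.v[s, 0].copy(),
            "yaw0": float(yaw_of(est.R[s, 0])),
        }

    def retract(self, est: Estimate, delta: np.ndarray) -> Estimate:
        K, S = self.K, self.S
        out = est.copy()
        st = delta[: self.n_state].reshape(K, S, 9).swapaxes(0, 1)
        out.R = est.R @ expm(st[..., 0:3])
        out.v = est.v + st[..., 3:6]
        out.p = est.p + st[..., 6:9]
        bias = delta[self.bias0: self.calib0].reshape(S, 6)
        out.bg = est.bg + bias[:, :3]
        out.ba = est.ba + bias[:, 3:]
        out.jc = est.jc + delta[self.calib0: self.calib0 + 36].reshape(12, 3)
        out.axes = est.axes + delta[self.calib0 + 36:].reshape(12, 3)
        return out

    # -- residuals and Jacobian ---------------------------------------------

    def residuals(self, est: Estimate, with_jacobian: bool = False):
        cfg = self.cfg
        K, S, M = self.K, self.S, self.M
        dt, Dt = self.dt, self.Dt
        g = np.array([0.0, 0.0, -cfg.gravity])
        r = np.zeros(self.n_residuals)
        vals_list, rows_list, cols_list = [], [], []

        # ---- inertial ----
        pre = preintegrate(self.gyro, self.accel, dt, est.bg[:, None, :], est.ba[:, None, :])
        Ri = est.R[:, :-1]
        Rj = est.R[:, 1:]
        RiT = np.swapaxes(Ri, -1, -2)
        Q = RiT @ Rj
        rR = logm(np.swapaxes(pre["DR"], -1, -2) @ Q)
        dv_w = est.v[:, 1:] - est.v[:, :-1] - g * Dt
        rv = np.einsum("skij,ski->skj", Ri, dv_w) - pre["Dv"]
        dp_w = est.p[:, 1:] - est.p[:, :-1] - est.v[:, :-1] * Dt - 0.5 * g * Dt * Dt
        rp = np.einsum("skij,ski->skj", Ri, dp_w) - pre["Dp"]
        s_r = cfg.sigma_gyro * np.sqrt(Dt * dt)
        s_v = cfg.sigma_accel * np.sqrt(Dt * dt)
        s_p = s_v * Dt
        n_in = S * (K - 1) * 9
        r[:n_in] = np.concatenate([rR / s_r, rv / s_v, rp / s_p], axis=-1).ravel()

        if with_jacobian:
            Jri = right_jacobian_inv(rR)
            ER = expm(rR)
            blk = np.zeros((S, K - 1, 9, 24))
            # rows 0:3 = rotation residual
            blk[..., 0:3, 0:3] = -(Jri @ np.swapaxes(Q, -1, -2))
            blk[..., 0:3, 9:12] = Jri
            blk[..., 0:3, 18:21] = -(Jri @ np.swapaxes(ER, -1, -2) @ pre["JRg"])
            # rows 3:6 = velocity residual
            blk[..., 3:6, 0:3] = hat(rv + pre["Dv"])
            blk[..., 3:6, 3:6] = -RiT
            blk[..., 3:6, 12:15] = RiT
            blk[..., 3:6, 18:21] = -pre["Jvg"]
            blk[..., 3:6, 21:24] = -pre["Jva"]
            # rows 6:9 = position residual
            blk[..., 6:9, 0:3] = hat(rp + pre["Dp"])
            blk[..., 6:9, 3:6] = -RiT * Dt
            blk[..., 6:9, 6:9] = -RiT
            blk[..., 6:9, 15:18] = RiT
            blk[..., 6:9, 18:21] = -pre["Jpg"]
            blk[..., 6:9, 21:24] = -pre["Jpa"]
            blk[..., 0:3, :] /= s_r
            blk[..., 3:6, :] /= s_v
            blk[..., 6:9, :] /= s_p
            vals_list.append(blk.ravel())
            rows_list.append(self._in_rows)
            cols_list.append(self._in_cols)
        row0 = n_in

        # ---- joint center ----
        n_jc = 6 * K * 3
        rjc = np.empty((6, K, 3))
        if with_jacobian:
            jblk = np.zeros((6, K, 3, 18))
        for j, (sA, sB, iA, iB) in enumerate(self._jc_meta):
            RA, RB = est.R[sA], est.R[sB]
            sa, sbv = est.jc[iA], est.jc[iB]
            rjc[j] = (est.p[sA] + RA @ sa - est.p[sB] - RB @ sbv) / cfg.sigma_jc
            if with_jacobian:
                eye = np.broadcast_to(np.eye(3), (K, 3, 3))
                jblk[j, :, :, 0:3] = -RA @ hat(sa)
                jblk[j, :, :, 3:6] = eye
                jblk[j, :, :, 6:9] = RB @ hat(sbv)
                jblk[j, :, :, 9:12] = -eye
                jblk[j, :, :, 12:15] = RA
                jblk[j, :, :, 15:18] = -RB
        r[row0: row0 + n_jc] = rjc.ravel()
        if with_jacobian:
            vals_list.append((jblk / cfg.sigma_jc).ravel())
            rows_list.append(self._jc_rows)
            cols_list.append(self._jc_cols)
        row0 += n_jc

        # ---- hinge ----
        nh = len(self._hinge_meta)
        n_h = nh * K * 3
        if nh:
            rh = np.empty((nh, K, 3))
            if with_jacobian:
                hblk = np.zeros((nh, K, 3, 12))
            for j, (sA, sB, iA, iB, sig) in enumerate(self._hinge_meta):
                RA, RB = est.R[sA], est.R[sB]
                aA, aB = est.axes[iA], est.axes[iB]
                rh[j] = (RA @ aA - RB @ aB) / sig
                if with_jacobian:
                    hblk[j, :, :, 0:3] = (-RA @ hat(aA)) / sig
                    hblk[j, :, :, 3:6] = (RB @ hat(aB)) / sig
                    hblk[j, :, :, 6:9] = RA / sig
                    hblk[j, :, :, 9:12] = -RB / sig
            r[row0: row0 + n_h] = rh.ravel()
            if with_jacobian:
                vals_list.append(hblk.ravel())
                rows_list.append(self._h_rows)
                cols_list.append(self._h_cols)
        row0 += n_h

        # ---- axis norms ----
        norms2 = np.einsum("ij,ij->i", est.axes, est.axes)
        r[row0: row0 + 12] = (norms2 - 1.0) / cfg.sigma_axis_norm
        if with_jacobian:
            vals_list.append((2.0 * est.axes / cfg.sigma_axis_norm).ravel())
            rows_list.append(self._norm_rows)
            cols_list.append(self._norm_cols)
        row0 += 12

        # ---- priors ----
        if self.gauge is None:
            self.set_gauge_from(est)
        pr_rows, pr_cols, pr_vals = [], [], []
        sL = _SID_INDEX["lumbar"]

        def add_block(rw, cw, vals, resid):
            nonlocal row0
            nr = len(resid)
            r[row0: row0 + nr] = resid
            if with_jacobian:
                pr_rows.append((row0 + rw).ravel())
                pr_cols.append(cw.ravel())
                pr_vals.append(vals.ravel())
            row0 += nr

        # bias priors (zero-mean)
        for s in range(S):
            add_block(
                np.arange(3)[:, None], np.full((3, 1), 0) + self._bg(s) + np.arange(3)[:, None],
                np.full(3, 1.0 / cfg.sigma_bias_gyro),
                est.bg[s] / cfg.sigma_bias_gyro,
            )
            add_block(
                np.arange(3)[:, None], self._ba(s) + np.arange(3)[:, None],
                np.full(3, 1.0 / cfg.sigma_bias_accel),
                est.ba[s] / cfg.sigma_bias_accel,
            )
        # gauge priors
        add_block(
            np.arange(3)[:, None], self._p(sL, 0) + np.arange(3)[:, None],
            np.full(3, 1.0 / cfg.sigma_gauge_pos),
            (est.p[sL, 0] - self.gauge["p0"]) / cfg.sigma_gauge_pos,
        )
        add_block(
            np.arange(3)[:, None], self._v(sL, 0) + np.arange(3)[:, None],
            np.full(3, 1.0 / cfg.sigma_gauge_vel),
            (est.v[sL, 0] - self.gauge["v0"]) / cfg.sigma_gauge_vel,
        )
        # heading gauge: 1 row, 3 theta cols
        R0 = est.R[sL, 0]
        cvec = R0[:, 0]
        dyaw_dc = np.array([-cvec[1], cvec[0], 0.0]) / (cvec[0] ** 2 + cvec[1] ** 2)
        dyaw_dth = -dyaw_dc @ R0 @ hat(np.array([1.0, 0.0, 0.0]))
        yerr = yaw_of(R0) - self.gauge["yaw0"]
        yerr = np.arctan2(np.sin(yerr), np.cos(yerr))
        add_block(
            np.zeros((1, 3), dtype=int) + 0,
            self._th(sL, 0) + np.arange(3)[None, :],
            dyaw_dth / cfg.sigma_gauge_yaw,
            np.array([yerr / cfg.sigma_gauge_yaw]),
        )
        # weak regularization of the non-hip joint-center vectors: bounds
        # their along-hinge-axis flat direction during pure hinge motion
        for key in JC_KEYS:
            if key in HIP_JC_KEYS:
                continue
            i = _JC_INDEX[key]
            add_block(
                np.arange(3)[:, None],
                self._jc(key) + np.arange(3)[:, None],
                np.full(3, 1.0 / cfg.sigma_jc_reg),
                est.jc[i] / cfg.sigma_jc_reg,
            )
        # hip-vector priors
        if self.priors is not None:
            for key in HIP_JC_KEYS:
                mean, cov = self.priors.hip_jc[key]
                Lw = np.linalg.inv(np.linalg.cholesky(cov))
                i = _JC_INDEX[key]
                add_block(
                    np.repeat(np.arange(3), 3),
                    np.tile(self._jc(key) + np.arange(3), 3),
                    Lw,
                    Lw @ (est.jc[i] - mean),
                )
        assert row0 == self.n_residuals, (row0, self.n_residuals)

        if not with_jacobian:
            return r
        rows = np.concatenate(rows_list + pr_rows)
        cols = np.concatenate(cols_list + pr_cols)
        vals = np.concatenate(vals_list + pr_vals)
        J = sp.coo_matrix(
            (vals, (rows, cols)), shape=(self.n_residuals, self.n_unknowns)
        ).tocsr()
        return r, J

    # -- extraction ---------------------------------------------------------

    def extract_solution(
        self, est: Estimate, cost: float, reason: str, iters: int,
        with_covariance: bool = False,
    ) -> Solution:
        trajs = {}
        for s, sid in enumerate(PLACEMENTS):
            trajs[sid] = StateTrajectory(
                sensor_id=sid,
                times=self.kf_times.copy(),
                R=est.R[s].copy(),
                v=est.v[s].copy(),
                p=est.p[s].copy(),
                bg=est.bg[s].copy(),
                ba=est.ba[s].copy(),
            )
        jc = {}
        axes = {}
        flips = _axis_sign_flips(est)
        for key in JC_KEYS:
            jc[key] = est.jc[_JC_INDEX[key]].copy()
        for key in AXIS_KEYS:
            a = est.axes[_AXIS_INDEX[key]]
            joint = key[1]
            a = a * flips[joint]
            axes[key] = a / np.linalg.norm(a)
        calib = CalibrationParameters(jc=jc, axes=axes)
        if with_covariance:
            calib.jc_cov = self._jc_covariance(est)
        return Solution(
            trajectories=trajs, calibration=calib, cost=cost,
            convergence=reason, iterations=iters, estimate=est, problem=self,
        )

    def _jc_covariance(self, est: Estimate) -> dict:
        _, J = self.residuals(est, with_jacobian=True)
        H = (J.T @ J).tocsc()
        n = self.n_unknowns
        H = H + sp.eye(n, format="csc") * 1e-9
        lu = spla.splu(H, permc_spec="NATURAL")
        cov = {}
        for key in JC_KEYS:
            i0 = self._jc(key)
            E = np.zeros((n, 3))
            E[i0: i0 + 3] = np.eye(3)
            X = lu.solve(E)
            cov[key] = X[i0: i0 + 3]
        return cov


def _axis_sign_flips(est: Estimate) -> dict[str, float]:
    """Sign convention for the (a, -a)-ambiguous hinge axes.

    The knee axis sign is chosen so the hinge angle (relative rotation
    projected on the axis) is predominantly positive — knees flex, they do
    not hyperextend; hip and ankle axes are then aligned (world frame, first
    keyframe) with their side's knee axis.
    """
    flips: dict[str, float] = {}
    world_knee: dict[str, np.ndarray] = {}
    for side in ("r", "l"):
        knee = f"knee_{side}"
        A, B = JOINT_PAIRS[knee]
        sA, sB = _SID_INDEX[A], _SID_INDEX[B]
        aA = est.axes[_AXIS_INDEX[(A, knee)]]
        rel = logm(np.swapaxes(est.R[sA], -1, -2) @ est.R[sB])
        mean_angle = float(np.mean(rel @ (aA / np.linalg.norm(aA))))
        flips[knee] = 1.0 if mean_angle >= 0 else -1.0
        world_knee[side] = est.R[sA, 0] @ (aA * flips[knee])
    for side in ("r", "l"):
        for joint in (f"hip_{side}", f"ankle_{side}"):
            A, _B = JOINT_PAIRS[joint]
            sA = _SID_INDEX[A]
            aA = est.axes[_AXIS_INDEX[(A, joint)]]
            w = est.R[sA, 0] @ aA
            flips[joint] = 1.0 if float(w @ world_knee[side]) >= 0 else -1.0
    return flips


# ---------------------------------------------------------------------------
# Levenberg-Marquardt
# ---------------------------------------------------------------------------


def assemble_problem(
    array: SensorArray,
    window: tuple[int, int] | None = None,
    priors: Priors | None = None,
    cfg: NoiseConfig | None = None,
    keyframe_rate: float = 20.0,
    kind: str = "calibration",
    hinge_joints: tuple[str, ...] = JOINTS,
) -> EstimationProblem:
    """Build the residual system for one sample-index window of a recording."""
    if window is not None:
        s, e = window
        if e <= s:
            raise ArgumentError("empty window")
        array = array.slice(s, e)
    return EstimationProblem(
        array, cfg=cfg, keyframe_rate=keyframe_rate, priors=priors,
        kind=kind, hinge_joints=hinge_joints,
    )


def solve_lm(
    problem: EstimationProblem,
    init: Estimate | None = None,
    max_iters: int = _MAX_ITERS,
    lam0: float = 1e-4,
    with_covariance: bool = False,
    verbose: bool = False,
) -> Solution:
    """Levenberg-Marquardt with the damped-normal-equations update.

    Terminates on an absolute cost change <= 1e-6, a relative cost change
    <= 1e-4, or ``max_iters`` iterations (default 10,000), whichever fires
    first; the convergence reason is recorded on the solution.  The cost over
    accepted steps is nonincreasing by construction.
    """
    est = problem.initial_estimate() if init is None else init.copy()
    if problem.gauge is None:
        problem.set_gauge_from(est)
    r = problem.residuals(est)
    if not np.all(np.isfinite(r)):
        raise InitializationError("non-finite residual at the initial estimate")
    F = 0.5 * float(r @ r)
    lam = lam0
    reason = "max_iterations"
    it = 0
    for it in range(1, max_iters + 1):
        r, J = problem.residuals(est, with_jacobian=True)
        H = (J.T @ J).tocsc()
        grad = J.T @ r
        D = H.diagonal().copy()
        D[D < 1e-12] = 1e-12
        accepted = False
        for _ in range(60):
            A = H + sp.diags(lam * D, format="csc")
            try:
                delta = spla.splu(A, permc_spec="NATURAL").solve(-grad)
            except RuntimeError:
                lam *= 10.0
                continue
            if not np.all(np.isfinite(delta)) or np.max(np.abs(delta)) > 1.0:
                # a step of 1 m / 1 rad / 1 m/s in a single component means
                # the damped system is numerically singular along a flat
                # direction: raise the damping instead of wandering
                lam *= 10.0
                continue
            est_try = problem.retract(est, delta)
            r_try = problem.residuals(est_try)
            if not np.all(np.isfinite(r_try)):
                lam *= 10.0
                continue
            F_try = 0.5 * float(r_try @ r_try)
            if F_try < F:
                accepted = True
                break
            lam *= 10.0
            if lam > 1e14:
                break
        if not accepted:
            # no improving step exists at any damping: stationary
            reason = "absolute"
            break
        dF = F - F_try
        est, F = est_try, F_try
        lam = max(lam / 3.0, 1e-12)
        if verbose:
            logger.info("LM iter %d cost %.6e dF %.3e lam %.1e", it, F, dF, lam)
        if dF <= _ABS_TOL:
            reason = "absolute"
            break
        if dF / max(F + dF, 1e-300) <= _REL_TOL:
            reason = "relative"
            break
    return problem.extract_solution(est, F, reason, it, with_covariance=with_covariance)


# ---------------------------------------------------------------------------
# task drivers
# ---------------------------------------------------------------------------


def hip_excitation_singular_values(sol: Solution) -> dict[str, np.ndarray]:
    """Per hip, singular values (rad) of the centered lumbar-to-thigh relative
    rotation-vector cloud — the excitation the calibration relies on."""
    out = {}
    for side in ("r", "l"):
        A, B = JOINT_PAIRS[f"hip_{side}"]
        RA = sol.trajectories[A].R
        RB = sol.trajectories[B].R
        rel = logm(np.swapaxes(RA, -1, -2) @ RB)
        rel = rel - rel.mean(axis=0)
        sv = np.linalg.svd(rel / np.sqrt(rel.shape[0]), compute_uv=False)
        out[side] = sv
    return out


UNDEREXCITATION_THRESHOLD = 0.05  # rad (~3 deg std along the weakest direction)


def run_calibration(
    array: SensorArray,
    cfg: NoiseConfig | None = None,
    keyframe_rate: float = 20.0,
    return_solution: bool = False,
):
    """Solve the full self-calibration problem on a calibration recording.

    No hip-vector priors are used (the motion itself must make them
    identifiable); the result carries Gauss-Newton covariances and, if the
    motion under-excites a hip's DOFs, an identifiability warning.

    Only the knee and ankle hinge residuals are applied: the loose hip
    pseudo-hinge exists to rescue relative heading during 1-DOF walking, and
    a proper calibration motion explores the hip's three DOFs, which both
    makes the hinge unnecessary and would give it a large misalignment floor.
    """
    problem = EstimationProblem(
        array, cfg=cfg, keyframe_rate=keyframe_rate, kind="calibration",
        hinge_joints=("knee_r", "knee_l", "ankle_r", "ankle_l"),
    )
    sol = solve_lm(problem, with_covariance=True)
    calib = sol.calibration
    sv = hip_excitation_singular_values(sol)
    for side, s in sv.items():
        if s[-1] < UNDEREXCITATION_THRESHOLD:
            msg = (
                f"hip_{side}: weakest relative-rotation excitation "
                f"{s[-1]:.3f} rad < {UNDEREXCITATION_THRESHOLD} rad; "
                "hip-center vectors may be non-identifiable"
            )
            calib.warnings.append(msg)
            logger.warning(msg)
    if return_solution:
        return calib, sol
    return calib


def run_walking(
    array: SensorArray,
    priors: Priors,
    cfg: NoiseConfig | None = None,
    n_windows: int = 60,
    keyframe_rate: float = 20.0,
    m_star: float = 0.05,
    drift_correction: bool = True,
) -> WalkingSolution:
    """Windowed walking estimation with hip-vector priors and the hip
    internal/external-rotation drift-correction heuristic.

    The recording is cut into ``n_windows`` near-equal subsets; each is
    solved independently and the per-window angle series are meant to be
    concatenated downstream.  Priors are mandatory: without them the walking
    problem is not identifiable (1-DOF hip kinematics).
    """
    if priors is None:
        raise ArgumentError(
            "walking estimation requires hip-vector priors from a calibration task"
        )
    from .drift import correction_loop  # deferred: drift imports this module
    from .io import plan_windows

    plan = plan_windows(array, n_windows)
    windows = []
    starts = []
    for (s, e) in plan.bounds:
        sub = array.slice(s, e)
        problem = EstimationProblem(sub, cfg=cfg, keyframe_rate=keyframe_rate,
                                    priors=priors, kind="walking")
        sol = solve_lm(problem)
        if drift_correction:
            sol = correction_loop(problem, sol, m_star=m_star)
        windows.append(sol)
        starts.append(float(array.t[s]))
    return WalkingSolution(windows=windows, window_start_times=starts)
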