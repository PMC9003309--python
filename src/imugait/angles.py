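"""Anatomical frames and 3-DOF joint angles from states + calibration.

The estimator yields sensor poses and sensor-frame calibration; clinically
meaningful angles need *anatomical* frames (x right, y anterior, z proximal).
The pelvis frame is built from the inter-hip-center direction (medial/lateral)
and the average gravity vertical seen by the lumbar sensor — the method has
no absolute pelvis reference, so a static bias against an external system is
expected and is removed downstream via the relative-alignment comparison.
Thigh/shank frames come from the joint-center vectors (longitudinal axis) and
the knee hinge axis (medial/lateral axis).

Hip angles follow the ISB (Wu) convention and knee angles the Grood-Suntay
joint coordinate system, both modified so +z is the proximal direction in all
segments; with e1 = proximal x and e3 = distal z this is the intrinsic x-y-z
Cardan decomposition.  Left-side ab/adduction and internal/external rotation
are sign-mirrored so positive means flexion / adduction / internal rotation
bilaterally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationParameters
from .errors import ArgumentError, DegenerateAxesError, SingularityError
from .estimator import Solution, WalkingSolution

_PARALLEL_TOL = 1e-6  # |sin(angle between axes)| below this is degenerate


@dataclass
class AnatomicalFrame:
    """Rotation with rows = (x right, y anterior, z proximal) unit vectors
    expressed in the source (sensor) frame; maps sensor coords to anatomical
    coords."""

    R: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ArgumentError("anatomical frame is not proper orthonormal")
        self.R = R


@dataclass
class PelvicVertical:
    """Average world-vertical direction expressed in the lumbar sensor frame."""

    v: np.ndarray
    window: float = 0.0  # s of data averaged

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        n = np.linalg.norm(v)
        if not np.isfinite(n) or n < 1e-12:
            raise ArgumentError("pelvic vertical must be a nonzero vector")
        self.v = v / n


@dataclass
class JointAngleSeries:
    """3-DOF joint angle time series (deg)."""

    t: np.ndarray
    flexion: np.ndarray
    abduction: np.ndarray  # positive = adduction (bilateral convention)
    internal: np.ndarray  # positive = internal rotation
    joint: str = ""
    side: str = ""
    convention: str = ""

    def __post_init__(self) -> None:
        for name in ("flexion", "abduction", "internal"):
            a = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(a)) or np.any(np.abs(a) >= 180.0):
                raise ArgumentError(f"{name} channel non-finite or out of range")
            setattr(self, name, a)

    def channel(self, name: str) -> np.ndarray:
        return {"fe": self.flexion, "aa": self.abduction, "ie": self.internal}[name]


def pcs_from_axes(x: np.ndarray, z: np.ndarray) -> AnatomicalFrame:
    """Orthonormal frame with the first row fixed parallel to ``x``, the third
    row ``z`` corrected for orthonormality, and the second row completing the
    right-handed set: rows are x^T, (z cross x)^T, (x cross (z cross x))^T,
    each normalized."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    nx, nz = np.linalg.norm(x), np.linalg.norm(z)
    if nx < 1e-8 or nz < 1e-8:
        raise DegenerateAxesError("(near-)zero-length axis")
    xh, zh = x / nx, z / nz
    y = np.cross(zh, xh)
    ny = np.linalg.norm(y)
    if ny < _PARALLEL_TOL:
        raise DegenerateAxesError("axes are (near-)parallel")
    yh = y / ny
    z3 = np.cross(xh, yh)
    z3 /= np.linalg.norm(z3)
    return AnatomicalFrame(R=np.stack([xh, yh, z3]))


def pelvic_vertical(
    lumbar_R: np.ndarray, times: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
) -> PelvicVertical:
    """Average of the world z-axis mapped into the lumbar sensor frame.

    ``lumbar_R`` is the (K, 3, 3) estimated lumbar orientation series; the
    optional time window (s) restricts the average (default: whole series).
    """
    R = np.asarray(lumbar_R, dtype=float)
    if window is not None:
        if times is None:
            raise ArgumentError("windowed averaging needs the time vector")
        lo, hi = window
        mask = (times >= lo) & (times <= hi)
        if not np.any(mask):
            raise ArgumentError("empty averaging window")
        R = R[mask]
    v = R[..., 2, :].mean(axis=0)  # rows of R^T: world z in the sensor frame
    span = 0.0 if times is None else float(times[-1] - times[0])
    return PelvicVertical(v=v, window=span)


def pelvis_orientation(
    calib: CalibrationParameters, v: PelvicVertical
) -> AnatomicalFrame:
    """Pelvis anatomical frame in the lumbar sensor frame: x from the
    normalized right-minus-left hip-center vector, z from the pelvic
    vertical."""
    d = calib.jc[("lumbar", "hip_r")] - calib.jc[("lumbar", "hip_l")]
    if np.linalg.norm(d) < 0.01:
        raise DegenerateAxesError("hip centers coincide in the lumbar frame")
    frame = pcs_from_axes(d, v.v)
    frame.source = "lumbar"
    return frame


def segment_frames(calib: CalibrationParameters) -> dict[str, AnatomicalFrame]:
    """Anatomical frames of thigh, shank and foot sensors.

    Thigh: z along (thigh->hip minus thigh->knee), x along the knee hinge
    axis; shank: z along (shank->knee minus shank->ankle), x along the knee
    axis in the shank frame; foot: z along foot->ankle, x along the ankle
    pseudo-axis.
    """
    out: dict[str, AnatomicalFrame] = {}
    for side in ("r", "l"):
        th = f"thigh_{side}"
        z = calib.jc[(th, f"hip_{side}")] - calib.jc[(th, f"knee_{side}")]
        if np.linalg.norm(z) < 1e-6:
            raise DegenerateAxesError(f"{th}: hip and knee vectors coincide")
        out[th] = pcs_from_axes(calib.axes[(th, f"knee_{side}")], z)
        out[th].source = th

        sh = f"shank_{side}"
        z = calib.jc[(sh, f"knee_{side}")] - calib.jc[(sh, f"ankle_{side}")]
        if np.linalg.norm(z) < 1e-6:
            raise DegenerateAxesError(f"{sh}: knee and ankle vectors coincide")
        out[sh] = pcs_from_axes(calib.axes[(sh, f"knee_{side}")], z)
        out[sh].source = sh

        ft = f"foot_{side}"
        z = calib.jc[(ft, f"ankle_{side}")]
        out[ft] = pcs_from_axes(calib.axes[(ft, f"ankle_{side}")], z)
        out[ft].source = ft
    return out


def cardan_e1_floating_e3(R_joint: np.ndarray, side: str = "r"):
    """Joint-coordinate-system decomposition of R_joint = R_prox^T R_dist.

    e1 = proximal x (medio-lateral), e3 = distal z (longitudinal), e2 the
    floating axis: the intrinsic x-y-z Cardan sequence.  Returns (flexion,
    ab/adduction, internal/external) in degrees; the left side's second and
    third angles are sign-mirrored so positive means adduction / internal
    rotation bilaterally.  Raises near the |ab/adduction| = 90 deg gimbal.
    """
    R = np.asarray(R_joint, dtype=float)
    single = R.ndim == 2
    if single:
        R = R[None]
    s2 = np.clip(R[..., 0, 2], -1.0, 1.0)
    if np.any(np.abs(np.abs(s2) - 1.0) < np.deg2rad(1e-6)):
        raise SingularityError("ab/adduction within 1e-6 deg of 90 deg (gimbal)")
    beta = np.arcsin(s2)
    alpha = np.arctan2(-R[..., 1, 2], R[..., 2, 2])
    gamma = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    sgn = 1.0 if side == "r" else -1.0
    out = (np.rad2deg(alpha), sgn * np.rad2deg(beta), sgn * np.rad2deg(gamma))
    if single:
        return tuple(float(a[0]) for a in out)
    return out


def compose_cardan(fe_deg, aa_deg, ie_deg, side: str = "r") -> np.ndarray:
    """Inverse of :func:`cardan_e1_floating_e3` (intrinsic x-y-z compose)."""
    from scipy.spatial.transform import Rotation

    sgn = 1.0 if side == "r" else -1.0
    ang = np.stack(
        [np.deg2rad(np.asarray(fe_deg, float)),
         sgn * np.deg2rad(np.asarray(aa_deg, float)),
         sgn * np.deg2rad(np.asarray(ie_deg, float))], axis=-1,
    )
    return Rotation.from_euler("XYZ", ang.reshape(-1, 3)).as_matrix().reshape(
        ang.shape[:-1] + (3, 3)
    )


def _world_frames(sol: Solution, calib: CalibrationParameters,
                  v: PelvicVertical | None):
    """World anatomical orientation series for pelvis, thighs, shanks."""
    if v is None:
        v = pelvic_vertical(sol.trajectories["lumbar"].R,
                            sol.trajectories["lumbar"].times)
    R_LLp = pelvis_orientation(calib, v).R
    frames = segment_frames(calib)
    world = {"pelvis": sol.trajectories["lumbar"].R @ R_LLp.T}
    for sid in ("thigh_r", "thigh_l", "shank_r", "shank_l"):
        world[sid] = sol.trajectories[sid].R @ frames[sid].R.T
    return world


def hip_angles(
    sol: Solution, v: PelvicVertical | None = None,
    calib: CalibrationParameters | None = None,
) -> dict[str, JointAngleSeries]:
    """ISB-convention hip angles (both sides) from a window solution.

    ``v`` defaults to the average vertical over the whole window;
    ``calib`` defaults to the solution's own calibration.
    """
    calib = calib or sol.calibration
    world = _world_frames(sol, calib, v)
    t = sol.trajectories["lumbar"].times
    out = {}
    for side in ("r", "l"):
        Rj = np.swapaxes(world["pelvis"], -1, -2) @ world[f"thigh_{side}"]
        fe, aa, ie = cardan_e1_floating_e3(Rj, side)
        out[side] = JointAngleSeries(
            t=t, flexion=fe, abduction=aa, internal=ie,
            joint="hip", side=side, convention="wu_modified",
        )
    return out


def knee_angles(
    sol: Solution, calib: CalibrationParameters | None = None
) -> dict[str, JointAngleSeries]:
    """Grood-Suntay knee angles (both sides) from a window solution."""
    calib = calib or sol.calibration
    world = _world_frames(sol, calib, None)
    t = sol.trajectories["lumbar"].times
    out = {}
    for side in ("r", "l"):
        Rj = np.swapaxes(world[f"thigh_{side}"], -1, -2) @ world[f"shank_{side}"]
        fe, aa, ie = cardan_e1_floating_e3(Rj, side)
        out[side] = JointAngleSeries(
            t=t, flexion=fe, abduction=aa, internal=ie,
            joint="knee", side=side, convention="grood_suntay",
        )
    return out


def concatenated_angles(
    wsol: WalkingSolution, joint: str = "knee"
) -> dict[str, JointAngleSeries]:
    """Concatenate per-window angle series of a windowed walking solution.

    Each window is derived with its own calibration and pelvic vertical (the
    windows were solved independently), then stitched on the trial timebase.
    """
    per_side: dict[str, list] = {"r": [], "l": []}
    times = []
    for sol, t0 in zip(wsol.windows, wsol.window_start_times):
        series = hip_angles(sol) if joint == "hip" else knee_angles(sol)
        times.append(sol.trajectories["lumbar"].times + t0)
        for side in ("r", "l"):
            per_side[side].append(series[side])
    t = np.concatenate(times)
    out = {}
    for side in ("r", "l"):
        out[side] = JointAngleSeries(
            t=t,
            flexion=np.concatenate([s.flexion for s in per_side[side]]),
            abduction=np.concatenate([s.abduction for s in per_side[side]]),
            internal=np.concatenate([s.internal for s in per_side[side]]),
            joint=joint, side=side,
            convention=per_side[side][0].convention,
        )
    return out


def truth_angle_series(trial, joint: str, side: str, sample_idx=None) -> JointAngleSeries:
    """Ground-truth profile channels of a synthetic trial as a JointAngleSeries."""
    a = trial.truth_angles.angles[f"{joint}_{side}"]
    t = trial.truth_angles.t
    if sample_idx is not None:
        a = a[sample_idx]
        t = t[sample_idx]
    return JointAngleSeries(
        t=t, flexion=a[:, 0], abduction=a[:, 1], internal=a[:, 2],
        joint=joint, side=side, convention="truth",
    )
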