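"""Static sensor-to-skeleton calibration containers.

The self-calibrating estimator recovers, per sensor frame, the static vectors
from each IMU origin to its adjacent joint centers and the (pseudo-)hinge axis
direction of each spanned joint.  Both are expressed in the sensor's own
coordinate frame and are constant while the sensor stays rigidly mounted.

Keys are ``(sensor_id, joint_id)`` pairs.  Joints are ``hip_r/hip_l`` (3-DOF
ball, loosely hinged), ``knee_r/knee_l`` (hinge) and ``ankle_r/ankle_l``
(loosely hinged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError

JOINTS = ("hip_r", "hip_l", "knee_r", "knee_l", "ankle_r", "ankle_l")

#: (proximal sensor, distal sensor) flanking each joint
JOINT_PAIRS: dict[str, tuple[str, str]] = {
    "hip_r": ("lumbar", "thigh_r"),
    "hip_l": ("lumbar", "thigh_l"),
    "knee_r": ("thigh_r", "shank_r"),
    "knee_l": ("thigh_l", "shank_l"),
    "ankle_r": ("shank_r", "foot_r"),
    "ankle_l": ("shank_l", "foot_l"),
}

#: the 12 joint-center vector slots, in canonical order
JC_KEYS: tuple[tuple[str, str], ...] = tuple(
    (sensor, joint) for joint in JOINTS for sensor in JOINT_PAIRS[joint]
)

#: the 12 hinge-axis slots, in canonical order
AXIS_KEYS: tuple[tuple[str, str], ...] = JC_KEYS

#: the four hip-connected joint-center vectors used as walking priors
HIP_JC_KEYS: tuple[tuple[str, str], ...] = (
    ("lumbar", "hip_r"),
    ("lumbar", "hip_l"),
    ("thigh_r", "hip_r"),
    ("thigh_l", "hip_l"),
)


@dataclass
class CalibrationParameters:
    """Joint-center vectors (m) and hinge axes (unit), per sensor frame.

    ``jc[(sensor, joint)]`` is the vector from the sensor origin to the joint
    center, in the sensor frame.  ``axes[(sensor, joint)]`` is the joint's
    hinge (or pseudo-hinge) axis direction in the sensor frame, unit norm.
    ``jc_cov`` holds 3x3 covariances for whichever vectors have them.
    """

    jc: dict[tuple[str, str], np.ndarray]
    axes: dict[tuple[str, str], np.ndarray]
    jc_cov: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for key in JC_KEYS:
            if key not in self.jc:
                raise ArgumentError(f"missing joint-center vector {key}")
            v = np.asarray(self.jc[key], dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ArgumentError(f"bad joint-center vector {key}")
            if np.linalg.norm(v) >= 1.0:
                raise ArgumentError(f"joint-center vector {key} magnitude >= 1 m")
            self.jc[key] = v
        for key in AXIS_KEYS:
            if key not in self.axes:
                raise ArgumentError(f"missing hinge axis {key}")
            a = np.asarray(self.axes[key], dtype=float)
            n = np.linalg.norm(a)
            if a.shape != (3,) or not np.isfinite(n) or n < 1e-9:
                raise ArgumentError(f"bad hinge axis {key}")
            self.axes[key] = a / n

    def hip_vectors(self) -> dict[tuple[str, str], np.ndarray]:
        """The four hip-connected joint-center vectors."""
        return {k: self.jc[k] for k in HIP_JC_KEYS}


@dataclass
class Priors:
    """Gaussian priors for the walking-task estimation problem.

    ``hip_jc`` maps each of the four hip-connected vector slots to a
    (mean, covariance) pair; these come from the calibration task.  The gauge
    priors (lumbar first-keyframe position, heading and velocity) are part of
    the problem assembly and not stored here.
    """

    hip_jc: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for key in HIP_JC_KEYS:
            if key not in self.hip_jc:
                raise ArgumentError(f"missing hip-vector prior {key}")
            mean, cov = self.hip_jc[key]
            mean = np.asarray(mean, dtype=float)
            cov = np.asarray(cov, dtype=float)
            if mean.shape != (3,) or cov.shape != (3, 3):
                raise ArgumentError(f"bad hip-vector prior {key}")
            w = np.linalg.eigvalsh(cov)
            if np.any(w <= 0):
                raise ArgumentError(f"hip-vector prior covariance {key} not positive definite")
            self.hip_jc[key] = (mean, cov)

    @classmethod
    def from_calibration(
        cls, calib: CalibrationParameters, inflation: float = 4.0
    ) -> "Priors":
        """Build walking priors from a calibration solution.

        Covariances are the calibration's Gauss-Newton covariances inflated by
        ``inflation`` (default x4) to hedge calibration-vs-walking soft-tissue
        differences; a 1 cm^2 diagonal fallback is used for vectors without a
        stored covariance.
        """
        priors = {}
        for key in HIP_JC_KEYS:
            cov = calib.jc_cov.get(key)
            if cov is None:
                cov = np.eye(3) * 1e-4
            priors[key] = (calib.jc[key].copy(), inflation * np.asarray(cov, dtype=float))
        return cls(hip_jc=priors)
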